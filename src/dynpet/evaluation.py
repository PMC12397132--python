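"""Statistical readouts of a simulated study: bias, noise-bias trade-off,
contrast-to-noise ratios and cross-configuration aggregates.

Conventions (documented because several flavors exist):

* percent bias of a label statistic is ``|(<estimate> - truth)/truth| * 100``
  where ``<.>`` is the mean across noise replicates (bias of the mean);
* the SD column is the sample SD (N-1) across replicates of the
  per-replicate percent bias;
* voxel-wise mean/SD volumes across replicates use the population SD (N);
* NBias is the bias of the replicate mean, NSD the sample SD of the
  replicate label means divided by truth, both in percent;
* CNR is ``|mean(tissue ROI) - mean(background ROI)| / SD(background ROI)``
  evaluated on the replicate-mean map, background = venous blood pool.

The printed reference bias tables of the validation study are packaged as
checksummed CSVs so the cross-configuration aggregation can be recomputed
without transcription drift.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PARAMS_2TCM = ["K1", "k2", "k3", "vb", "Ki"]
PARAMS_PATLAK = ["Ki", "vb"]


class UndefinedCNRError(ValueError):
    """Raised when the background ROI has zero variance."""


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _read_packaged_csv(name: str) -> pd.DataFrame:
    pkg = resources.files("dynpet") / "data"
    raw = (pkg / name).read_bytes()
    with (pkg / "checksums.json").open() as fh:
        expected = json.load(fh)[name]
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise RuntimeError(f"packaged table {name} failed its checksum")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw))


def load_reference_bias_tables() -> Dict[int, pd.DataFrame]:
    """Published per-structure bias tables, keyed by OSEM iteration count.

    Columns: config (SAFOV/LAFOV), structure, model (2tcm/patlak),
    parameter, bias_pct, sd_pct.
    """
    return {2: _read_packaged_csv("reference_bias_2iter.csv"),
            6: _read_packaged_csv("reference_bias_6iter.csv")}


# ---------------------------------------------------------------------------
# Voxel-wise replicate statistics
# ---------------------------------------------------------------------------

def label_mean_map(maps: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Voxel-wise mean and population SD across replicate maps."""
    if len(maps) < 2:
        raise ValueError("need at least 2 replicates")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    if any(m.shape != stack.shape[1:] for m in maps):
        raise ValueError("replicate maps must share one grid")
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def label_stat(map3d: np.ndarray, label_grid: np.ndarray, label: int,
               reducer=np.nanmean) -> float:
    """One scalar statistic of a map over a label's voxels."""
    vals = np.asarray(map3d)[label_grid == label]
    if vals.size == 0:
        raise ValueError(f"label {label} has no voxels")
    return float(reducer(vals))


def percent_bias(estimate: float, truth: float) -> float:
    """``|(estimate - truth)/truth| * 100``."""
    if truth == 0:
        raise ZeroDivisionError("truth is zero")
    return abs((estimate - truth) / truth) * 100.0


# ---------------------------------------------------------------------------
# Bias tables
# ---------------------------------------------------------------------------

def bias_per_label(replicate_stats: np.ndarray, truth: float) -> Tuple[float, float]:
    """(bias of the replicate mean, sample SD of per-replicate biases), %."""
    reps = np.asarray(replicate_stats, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("no finite replicate statistics")
    mean_bias = percent_bias(reps.mean(), truth)
    per_rep = np.abs((reps - truth) / truth) * 100.0
    sd = float(per_rep.std(ddof=1)) if reps.size > 1 else 0.0
    return mean_bias, sd


def bias_table(replicate_label_stats: pd.DataFrame, truths: pd.Series,
               config_tag: str = "") -> pd.DataFrame:
    """Assemble a bias table from per-replicate label statistics.

    ``replicate_label_stats``: rows = replicates, columns = MultiIndex
    (structure, parameter); ``truths``: per (structure, parameter) ground
    truth.  Cells with zero truth are excluded and listed in the
    ``excluded`` attribute of the returned frame.
    """
    rows, excluded = [], []
    for key in replicate_label_stats.columns:
        truth = truths[key]
        if truth == 0 or not np.isfinite(truth):
            excluded.append(key)
            continue
        b, sd = bias_per_label(replicate_label_stats[key].to_numpy(), truth)
        structure, parameter = key
        rows.append({"structure": structure, "parameter": parameter,
                     "bias_pct": b, "sd_pct": sd,
                     "n_replicates": len(replicate_label_stats),
                     "config": config_tag})
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def noise_bias_tradeoff(replicate_label_stats: pd.DataFrame, truths: pd.Series,
                        iterations: int, config_tag: str = "") -> pd.DataFrame:
    """Noise-bias trade-off points: NBias vs NSD per (structure, parameter)."""
    rows = []
    for key in replicate_label_stats.columns:
        truth = truths[key]
        if truth == 0 or not np.isfinite(truth):
            continue
        reps = replicate_label_stats[key].to_numpy(dtype=float)
        reps = reps[np.isfinite(reps)]
        structure, parameter = key
        rows.append({
            "structure": structure, "parameter": parameter,
            "nbias_pct": percent_bias(reps.mean(), truth),
            "nsd_pct": abs(reps.std(ddof=1) / truth) * 100.0,
            "iterations": iterations, "config": config_tag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------

def cnr(map3d: np.ndarray, tissue_mask: np.ndarray,
        background_mask: np.ndarray, min_background: int = 10) -> float:
    """Absolute contrast-to-noise ratio against a background ROI.

    ``|mean(tissue) - mean(bck)| / SD(bck)`` on the supplied (replicate-mean)
    map; the background must be at least ``min_background`` voxels.
    Identical ROIs give zero contrast, hence CNR 0.
    """
    t = np.asarray(tissue_mask, dtype=bool)
    b = np.asarray(background_mask, dtype=bool)
    if b.sum() < min_background:
        raise ValueError(f"background ROI smaller than {min_background} voxels")
    m = np.asarray(map3d, dtype=float)
    sd = float(np.nanstd(m[b], ddof=0))
    if sd == 0 or not np.isfinite(sd):
        raise UndefinedCNRError("background ROI has zero variance")
    return abs(float(np.nanmean(m[t])) - float(np.nanmean(m[b]))) / sd


def cnr_table(mean_maps: Dict[Tuple[str, str], np.ndarray],
              tissue_masks: Dict[str, np.ndarray],
              background_mask: np.ndarray) -> pd.DataFrame:
    """CNR per (structure, map) from replicate-mean maps.

    ``mean_maps`` keys are (map_type, parameter), e.g. ("patlak", "Ki") or
    ("suv", "SUV").  Undefined cells are kept with NaN and flagged.
    """
    rows = []
    for (map_type, parameter), vol in mean_maps.items():
        for structure, mask in tissue_masks.items():
            try:
                val = cnr(vol, mask, background_mask)
                defined = True
            except (UndefinedCNRError, ValueError):
                val, defined = np.nan, False
            rows.append({"structure": structure, "map_type": map_type,
                         "parameter": parameter, "cnr": val,
                         "defined": defined,
                         "n_background": int(np.asarray(background_mask).sum())})
    return pd.DataFrame(rows)


def kinetic_to_suv_cnr_ratio(kinetic: pd.DataFrame,
                             suv_table: pd.DataFrame) -> pd.DataFrame:
    """Per-structure ratio of kinetic CNR to SUV CNR.

    Rows whose SUV CNR is zero or undefined are retained with a NaN ratio
    and ``defined = False``.
    """
    suv_by_struct = suv_table.set_index("structure")["cnr"]
    out = kinetic.copy()
    denom = out["structure"].map(suv_by_struct)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cnr_suv"] = denom
        out["ratio"] = np.where((denom > 0) & np.isfinite(denom),
                                out["cnr"] / denom, np.nan)
    out["defined"] = np.isfinite(out["ratio"])
    return out


# ---------------------------------------------------------------------------
# Cross-configuration aggregation
# ---------------------------------------------------------------------------

def median_relative_bias_change(bias_safov: pd.DataFrame,
                                bias_lafov: pd.DataFrame,
                                parameters: Iterable[str],
                                model: Optional[str] = None) -> float:
    """Median percent change of per-cell bias between two configurations.

    Per (structure, parameter) cell: ``100 * (bias_L - bias_S)/bias_S``;
    the return value is the median over all cells of the chosen parameter
    set (even counts: mean of the central pair).  Cells with zero baseline
    bias are excluded (and recorded in ``.attrs`` would-be callers can log).
    Round to the nearest integer for reporting.
    """
    params = list(parameters)

    def cells(df: pd.DataFrame) -> pd.Series:
        d = df[df["parameter"].isin(params)]
        if model is not None and "model" in d.columns:
            d = d[d["model"] == model]
        return d.set_index(["structure", "parameter"])["bias_pct"]

    s = cells(bias_safov)
    l = cells(bias_lafov)
    if set(s.index) != set(l.index):
        raise ValueError("configurations cover different (structure, parameter) cells")
    l = l.reindex(s.index)
    ok = s != 0
    change = 100.0 * (l[ok] - s[ok]) / s[ok]
    return float(np.median(change.to_numpy()))


def reference_median_bias_changes() -> pd.DataFrame:
    """Recompute the cross-configuration medians from the packaged tables."""
    tables = load_reference_bias_tables()
    rows = []
    for iters, df in tables.items():
        s = df[df["config"] == "SAFOV"]
        l = df[df["config"] == "LAFOV"]
        for model, params in (("patlak", PARAMS_PATLAK), ("2tcm", PARAMS_2TCM)):
            med = median_relative_bias_change(s, l, params, model=model)
            rows.append({"model": model, "iterations": iters,
                         "median_change_pct": med,
                         "median_change_pct_rounded": int(round(med))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------

def plot_tradeoff(points: pd.DataFrame, path) -> None:
    """Noise-bias trade-off lines, one per structure, styled by config."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    for (structure, config), grp in points.groupby(["structure", "config"]):
        grp = grp.sort_values("iterations")
        ax.plot(grp["nsd_pct"], grp["nbias_pct"],
                marker="o", ls="--" if "safov" in str(config).lower() else "-",
                label=f"{structure} ({config})")
    ax.set_xlabel("NSD (%)")
    ax.set_ylabel("NBias (%)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cnr_ratios(ratios: pd.DataFrame, path) -> None:
    """Bar chart of kinetic-to-SUV CNR ratios with the parity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    d = ratios[ratios["defined"]].copy()
    d["cell"] = d["structure"] + "\n" + d["map_type"] + ":" + d["parameter"]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(d)), 4))
    ax.bar(range(len(d)), d["ratio"].to_numpy())
    ax.axhline(1.0, color="red", lw=1)
    ax.set_xticks(range(len(d)), d["cell"], rotation=90, fontsize=5)
    ax.set_ylabel("CNR kinetic / CNR SUV")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
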