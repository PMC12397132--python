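"""Study-level orchestration: fit every replicate of a simulated study and
assemble bias, noise-bias trade-off and CNR tables.

Ground truth per (structure, parameter):

* 2TCM parameters: the packaged per-tissue reference values (Ki as the
  macro influx constant);
* Patlak parameters: the same closed-form fit applied to the noise-free
  label TACs (the graphical slope of a voxel signal is (1-vb)*Ki, so the
  Patlak reference is computed, not copied from the compartment values);
* SUV: the noise-free last-frame label value converted to SUV.

CNR uses the eroded structure label as tissue ROI and the eroded venous
blood pool as background, on the voxel-wise mean across replicate maps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import evaluation as ev
from .fitting import (FitSettings, ParametricMaps, compute_suv_map,
                      extract_idif, fit_2tcm_voxelwise, fit_patlak_voxelwise)
from .kinetics import (InputFunction, TissueTAC, fit_patlak_line,
                       patlak_transform, suv)
from .phantom import (DynamicImage, PhantomSpec, TISSUE_STRUCTURES,
                      label_tacs)
from .schedule import FrameSchedule

DOSE_MBQ, WEIGHT_KG = 240.0, 60.0


def _eroded_mask(mask: np.ndarray, radius: int = 1,
                 min_voxels: int = 10) -> np.ndarray:
    """Erode an ROI to limit edge contamination; keep it usable on coarse grids."""
    if radius <= 0:
        return mask
    er = ndimage.binary_erosion(mask, iterations=radius)
    return er if er.sum() >= min_voxels else mask


def small_roi(mask: np.ndarray, n_voxels: int = 32) -> np.ndarray:
    """Deterministic small ROI: the ``n_voxels`` deepest voxels of a label.

    Depth is the Euclidean distance to the label boundary, so the ROI sits
    in the structure core, away from spill-over; ties break by array order.
    """
    mask = np.asarray(mask, dtype=bool)
    depth = ndimage.distance_transform_edt(mask)
    flat = np.argsort(-depth, axis=None, kind="stable")[:min(n_voxels, int(mask.sum()))]
    out = np.zeros(mask.shape, dtype=bool)
    out[np.unravel_index(flat, mask.shape)] = True
    return out & mask


def cnr_study(phantom: PhantomSpec, replicates: Sequence[DynamicImage],
              settings: Optional[FitSettings] = None,
              roi_voxels: int = 32) -> pd.DataFrame:
    """Kinetic-to-SUV CNR ratio table from small core ROIs.

    Mirrors the published analysis design: small regions of interest per
    tissue structure, the venous blood pool as background, CNR evaluated on
    the voxel-wise mean across many noise replicates.  Only ROI voxels are
    fitted, which keeps many-replicate studies tractable.
    """
    s = settings or FitSettings()
    label_of = {d.name: l for l, d in phantom.label_table.items()}
    rois = {name: small_roi(phantom.mask(label_of[name]), roi_voxels)
            for name in TISSUE_STRUCTURES}
    bck = small_roi(phantom.mask(phantom.venous_label), roi_voxels)
    fit_mask = bck.copy()
    for m in rois.values():
        fit_mask |= m

    acc: Dict[Tuple[str, str], list] = {}
    for dyn in replicates:
        inp, _ = extract_idif(dyn, phantom.mask(phantom.arterial_label))
        maps = {
            "patlak": fit_patlak_voxelwise(dyn, inp, s),
            "2tcm": fit_2tcm_voxelwise(dyn, inp, s, voxel_mask=fit_mask),
            "suv": compute_suv_map(dyn, DOSE_MBQ, WEIGHT_KG),
        }
        for model, pm in maps.items():
            for pname, vol in pm.params.items():
                acc.setdefault((model, pname), []).append(vol)
    mean_maps = {k: ev.label_mean_map(v)[0] for k, v in acc.items()}
    table = ev.cnr_table(mean_maps, rois, bck)
    kinetic = table[table["map_type"] != "suv"]
    suv_tab = table[table["map_type"] == "suv"]
    return ev.kinetic_to_suv_cnr_ratio(kinetic, suv_tab)


def patlak_reference(phantom: PhantomSpec, schedule: FrameSchedule,
                     inp: InputFunction,
                     settings: Optional[FitSettings] = None) -> pd.DataFrame:
    """Per-structure Patlak (Ki, vb) ground truth from noise-free TACs."""
    s = settings or FitSettings()
    tacs = label_tacs(phantom, schedule, inp)
    sel = schedule.mid_min >= s.t_star_min
    rows = []
    for label, d in phantom.label_table.items():
        if d.tissue_class != "tissue":
            continue
        tac = TissueTAC(tacs[label], schedule)
        x, y, used = patlak_transform(tac, inp)
        keep = sel & used
        p = fit_patlak_line(x[keep], y[keep],
                            s.frame_weights(schedule)[keep])
        rows.append({"structure": d.name, "Ki": p.Ki_slope, "vb": p.v_intercept})
    return pd.DataFrame(rows).set_index("structure")


def truth_values(phantom: PhantomSpec, schedule: FrameSchedule,
                 inp: InputFunction,
                 settings: Optional[FitSettings] = None) -> pd.Series:
    """Ground truth per (structure, model, parameter) as a Series."""
    out = {}
    for label, d in phantom.label_table.items():
        if d.tissue_class != "tissue":
            continue
        p = d.params
        out[(d.name, "2tcm", "K1")] = p.K1
        out[(d.name, "2tcm", "k2")] = p.k2
        out[(d.name, "2tcm", "k3")] = p.k3
        out[(d.name, "2tcm", "vb")] = p.vb
        out[(d.name, "2tcm", "Ki")] = p.ki
    pref = patlak_reference(phantom, schedule, inp, settings)
    for structure, row in pref.iterrows():
        out[(structure, "patlak", "Ki")] = row["Ki"]
        out[(structure, "patlak", "vb")] = row["vb"]
    tacs = label_tacs(phantom, schedule, inp)
    t_last = float(schedule.mid_min[-1])
    for label, d in phantom.label_table.items():
        if d.tissue_class != "tissue":
            continue
        out[(d.name, "suv", "SUV")] = float(
            suv(tacs[label][-1], DOSE_MBQ, WEIGHT_KG, t_last))
    s = pd.Series(out)
    s.index.names = ["structure", "model", "parameter"]
    return s


def fit_replicate(dyn: DynamicImage, phantom: PhantomSpec,
                  settings: Optional[FitSettings] = None,
                  models: str = "both") -> Dict[str, ParametricMaps]:
    """IDIF extraction plus Patlak/2TCM/SUV maps for one 4-D volume."""
    s = settings or FitSettings()
    inp, _ = extract_idif(dyn, phantom.mask(phantom.arterial_label))
    maps: Dict[str, ParametricMaps] = {}
    if models in ("patlak", "both"):
        maps["patlak"] = fit_patlak_voxelwise(dyn, inp, s)
    if models in ("2tcm", "both"):
        maps["2tcm"] = fit_2tcm_voxelwise(dyn, inp, s)
    maps["suv"] = compute_suv_map(dyn, DOSE_MBQ, WEIGHT_KG)
    return maps


def evaluate_replicates(phantom: PhantomSpec, replicates: Sequence[DynamicImage],
                        inp_truth: InputFunction,
                        settings: Optional[FitSettings] = None,
                        models: str = "both", iterations: int = 0,
                        config_tag: str = "") -> Dict[str, pd.DataFrame]:
    """Fit every replicate and assemble the study tables.

    Returns ``{"bias": ..., "tradeoff": ..., "cnr": ..., "cnr_ratio": ...,
    "label_stats": ...}``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    schedule = replicates[0].schedule
    s = settings or FitSettings()
    truths = truth_values(phantom, schedule, inp_truth, s)

    rep_maps = [fit_replicate(d, phantom, s, models) for d in replicates]

    grid = phantom.label_grid
    label_of = {d.name: l for l, d in phantom.label_table.items()}
    # per-replicate label-mean statistics
    stats_rows = []
    for r, maps in enumerate(rep_maps):
        row = {}
        for model, pm in maps.items():
            for pname, vol in pm.params.items():
                for structure in TISSUE_STRUCTURES:
                    row[(structure, model, pname)] = ev.label_stat(
                        vol, grid, label_of[structure])
        stats_rows.append(pd.Series(row, name=r))
    stats = pd.DataFrame(stats_rows)
    stats.columns = pd.MultiIndex.from_tuples(stats.columns,
                                              names=["structure", "model",
                                                     "parameter"])

    bias_frames, tradeoff_frames = [], []
    for model in {m for (_, m, _) in stats.columns}:
        sub = stats.loc[:, (slice(None), model, slice(None))]
        sub.columns = pd.MultiIndex.from_tuples(
            [(a, c) for a, _, c in sub.columns])
        tr = truths.xs(model, level="model")
        b = ev.bias_table(sub, tr, config_tag=config_tag)
        b["model"] = model
        bias_frames.append(b)
        t = ev.noise_bias_tradeoff(sub, tr, iterations, config_tag)
        t["model"] = model
        tradeoff_frames.append(t)
    bias = pd.concat(bias_frames, ignore_index=True)
    tradeoff = pd.concat(tradeoff_frames, ignore_index=True)

    # CNR on replicate-mean maps, venous blood pool as background
    mean_maps: Dict[Tuple[str, str], np.ndarray] = {}
    for model in rep_maps[0]:
        for pname in rep_maps[0][model].params:
            mean_maps[(model, pname)], _ = ev.label_mean_map(
                [m[model][pname] for m in rep_maps])
    tissue_masks = {name: _eroded_mask(phantom.mask(label_of[name]))
                    for name in TISSUE_STRUCTURES}
    bck = _eroded_mask(phantom.mask(phantom.venous_label))
    cnr_all = ev.cnr_table(mean_maps, tissue_masks, bck)
    kinetic = cnr_all[cnr_all["map_type"] != "suv"]
    suv_tab = cnr_all[cnr_all["map_type"] == "suv"]
    ratio = ev.kinetic_to_suv_cnr_ratio(kinetic, suv_tab)
    return {"bias": bias, "tradeoff": tradeoff, "cnr": cnr_all,
            "cnr_ratio": ratio, "label_stats": stats}


# ---------------------------------------------------------------------------
# On-disk studies
# ---------------------------------------------------------------------------

def evaluate_study(study_dir, out_dir, models: str = "both",
                   max_replicates: Optional[int] = None,
                   settings: Optional[FitSettings] = None) -> Dict[str, pd.DataFrame]:
    """Evaluate a study directory written by :func:`dynpet.simulate.simulate_study`.

    Writes bias / trade-off / CNR / CNR-ratio CSVs and a JSON summary to
    ``out_dir`` and returns the tables.
    """
    from . import io as dio
    from .phantom import PhantomSpec, _default_label_table

    study = Path(study_dir)
    manifest = json.loads((study / "manifest.json").read_text())
    label_grid = dio.read_label_nifti(study / "labels.nii")
    phantom = PhantomSpec(label_grid, _default_label_table(),
                          tuple(manifest["voxel_size_mm"]))
    inp = InputFunction.from_csv(study / "input_function.csv")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: Dict[str, List[pd.DataFrame]] = {}
    for arm in manifest["arms"]:
        tag = f"{arm['config']['name']}_{arm['iterations']}it"
        rep_files = arm["replicates"][:max_replicates]
        reps = [dio.read_dynamic_nifti(study / f, study / "schedule.txt")
                for f in rep_files]
        tables = evaluate_replicates(phantom, reps, inp, settings, models,
                                     iterations=arm["iterations"],
                                     config_tag=arm["config"]["name"])
        for name in ("bias", "tradeoff", "cnr", "cnr_ratio"):
            df = tables[name].copy()
            df["arm"] = tag
            collected.setdefault(name, []).append(df)
    result = {k: pd.concat(v, ignore_index=True) for k, v in collected.items()}
    for name, df in result.items():
        df.to_csv(out / f"{name}.csv", index=False)
    summary = {name: int(len(df)) for name, df in result.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return result
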