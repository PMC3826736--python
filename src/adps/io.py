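"""Format handling, masking/vectorization, configuration and the pipeline.

NIfTI-1 volumes carry images, masks and discriminative maps; CSV tables
carry the cohort, cognitive battery, scores and result tables; JSON carries
ground truth and the run manifest. ``run_pipeline`` ties the modules into
the full workflow: nested-CV performance per modality, anchor + holdout
AD-PS scores, composites and risk zones, discriminative maps, stratified
comparison tables and the survival association — writing every artifact
with a manifest that records the seed and configuration hash so a rerun
reproduces all outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .linear_model import FeatureMatrix
from .maps import TissueMask, stability_ratio, to_volume, vectorize_volume, weight_ensemble
from .model_selection import SearchGrid
from .scoring import (
    MODALITY_ORDER,
    composite,
    hypercube_points,
    risk_zones,
    score_anchor_classes,
    score_holdout_group,
)
from .stats import SurvivalRecords, cox_fit, stratified_table
from .synthetic import Cohort, GroundTruth, SyntheticCohortSpec, generate_cohort

logger = logging.getLogger("adps")

__all__ = [
    "RunConfig",
    "build_mask",
    "vectorize",
    "save_volume",
    "load_volume",
    "write_cohort",
    "read_cohort",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; every protocol constant is a default here,
    never hard-coded downstream."""

    modalities: tuple = MODALITY_ORDER
    K1: int = 10
    K2: int = 10
    repetitions: int = 100
    seed: int = 0
    fixed_alpha: float = 0.1          # imaging modalities fix alpha
    n_lambda: int = 20
    lambda_min_ratio: Optional[float] = None
    mask_threshold: float = 0.5
    risk_threshold: float = 0.5
    age_cutoff: float = 75.0
    faq_cutoff: float = 2.0
    selection_rule: str = "best"
    tol: float = 1e-7
    map_repetitions: Optional[int] = None   # defaults to `repetitions`

    def __post_init__(self):
        if self.K1 < 2 or self.K2 < 2:
            raise ValueError("K1 and K2 must be >= 2")
        for name in ("mask_threshold", "risk_threshold", "age_cutoff", "faq_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        object.__setattr__(self, "modalities", tuple(self.modalities))

    def grid_for(self, modality: str) -> SearchGrid:
        kind = "cognitive" if modality == "cognitive" else "voxel"
        return SearchGrid.for_modality(
            kind, fixed_alpha=self.fixed_alpha,
            n_lambda=self.n_lambda, lambda_min_ratio=self.lambda_min_ratio,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# masks and volumes


def build_mask(template, threshold: float = 0.5, affine=None) -> TissueMask:
    """Threshold a tissue-probability template into a mask.

    A voxel enters the mask iff its template value is strictly greater than
    the threshold (values exactly at the threshold are excluded).
    """
    if isinstance(template, (str, Path)):
        img = nib.load(str(template))
        data = np.asarray(img.get_fdata())
        affine = img.affine
    elif hasattr(template, "get_fdata"):
        data = np.asarray(template.get_fdata())
        affine = template.affine
    else:
        data = np.asarray(template, dtype=float)
        if affine is None:
            affine = np.eye(4)
    if data.ndim != 3:
        raise ValueError("mask template must be a 3-D volume")
    return TissueMask(data > threshold, np.asarray(affine, dtype=float))


def vectorize(volumes, mask: TissueMask, subject_ids: Optional[Sequence] = None) -> FeatureMatrix:
    """Stack per-subject volumes into a subjects x voxels FeatureMatrix.

    Row i holds subject i's masked voxels in the fixed scan order; the
    round trip through ``maps.to_volume`` is exact. An empty mask is an
    error rather than a zero-column matrix.
    """
    if mask.voxel_count == 0:
        raise ValueError("mask is empty; refusing to build a 0-column matrix")
    vols = list(volumes)
    rows = []
    for i, vol in enumerate(vols):
        vol = np.asarray(vol)
        if vol.shape != mask.shape:
            who = subject_ids[i] if subject_ids is not None else f"subject #{i}"
            raise ValueError(f"volume shape {vol.shape} does not match mask for {who}")
        rows.append(vectorize_volume(vol, mask))
    return FeatureMatrix(np.asarray(rows), tuple(range(mask.voxel_count)), "voxel")


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


# ---------------------------------------------------------------------------
# cohort persistence


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a generated cohort in the formats the pipeline reads.

    Per tissue: a 4-D NIfTI (x, y, z, subject) plus its mask; CSVs for the
    subject table, cognitive battery and survival records; a JSON sidecar
    with the retained ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    files["subjects"] = "subjects.csv"
    cog = pd.DataFrame(cohort.cognitive.values, columns=list(cohort.cognitive.column_ids))
    cog.insert(0, "subject_id", cohort.subjects["subject_id"])
    cog.to_csv(out / "cognitive.csv", index=False)
    files["cognitive"] = "cognitive.csv"
    cohort.survival.to_csv(out / "survival.csv", index=False)
    files["survival"] = "survival.csv"
    for tissue, fm in cohort.images.items():
        mask = cohort.masks[tissue]
        vols = np.stack([to_volume(row, mask) for row in fm.values], axis=-1)
        save_volume(vols, mask.affine, out / f"{tissue}_images.nii.gz")
        save_volume(mask.flags.astype(np.float32), mask.affine, out / f"{tissue}_mask.nii.gz")
        files[f"{tissue}_images"] = f"{tissue}_images.nii.gz"
        files[f"{tissue}_mask"] = f"{tissue}_mask.nii.gz"
    truth = {
        "planted_indices": {t: np.asarray(v).tolist() for t, v in cohort.truth.planted_indices.items()},
        "severity": cohort.truth.severity.tolist(),
        "survival_params": cohort.truth.survival_params,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    files["ground_truth"] = "ground_truth.json"
    return files


def read_cohort(cohort_dir) -> Cohort:
    """Load a cohort directory written by ``write_cohort``.

    Missing files are reported by name at load time, before any compute.
    """
    d = Path(cohort_dir)
    required = ["subjects.csv", "cognitive.csv", "survival.csv"]
    for name in required:
        if not (d / name).exists():
            raise FileNotFoundError(f"cohort is missing required file: {d / name}")
    subjects = pd.read_csv(d / "subjects.csv")
    cog_df = pd.read_csv(d / "cognitive.csv")
    cognitive = FeatureMatrix(
        cog_df.drop(columns=["subject_id"]).to_numpy(float),
        tuple(cog_df.columns.drop("subject_id")),
        "cognitive",
    )
    survival = pd.read_csv(d / "survival.csv")
    images, masks = {}, {}
    for tissue in ("GM", "WM", "CSF"):
        ipath, mpath = d / f"{tissue}_images.nii.gz", d / f"{tissue}_mask.nii.gz"
        if not ipath.exists() or not mpath.exists():
            raise FileNotFoundError(f"cohort is missing modality file: {ipath if not ipath.exists() else mpath}")
        mdata, maff = load_volume(mpath)
        mask = TissueMask(mdata > 0.5, maff)
        vols, _ = load_volume(ipath)
        images[tissue] = vectorize(
            (vols[..., i] for i in range(vols.shape[-1])), mask,
            subject_ids=list(subjects["subject_id"]),
        )
        masks[tissue] = mask
    truth = None
    tpath = d / "ground_truth.json"
    if tpath.exists():
        raw = json.loads(tpath.read_text())
        truth = GroundTruth(
            {t: np.asarray(v, dtype=int) for t, v in raw["planted_indices"].items()},
            np.asarray(raw["severity"], dtype=float),
            raw.get("survival_params"),
        )
    return Cohort(None, subjects, images, masks, cognitive, survival, truth)


# ---------------------------------------------------------------------------
# pipeline


def _seed_for(base_seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cohort: Cohort, config: RunConfig, out_dir) -> dict:
    """Execute the full AD-PS workflow on a cohort and write all artifacts.

    Per modality: nested-CV performance on the anchor classes, out-of-fold
    anchor scores and full-model holdout (MCI) scores; then composites and
    hypercube risk zones, discriminative maps for the imaging tissues,
    stratified median/KS tables (clinical status, age, functional status)
    and the proportional-hazards association of every metric with
    conversion time. Returns the result bundle; a stage failure aborts with
    the stage name after persisting completed outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = cohort.groups
    anchor = cohort.anchor_mask()
    holdout = cohort.holdout_mask()
    y = cohort.anchor_labels()
    subject_id = cohort.subjects["subject_id"].to_numpy()
    results: dict = {"scores": {}, "performance": {}}
    written: list = []
    stage = "init"

    def _write_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(name)

    try:
        score_rows, perf_frames, fold_frames = [], [], []
        full_scores = {}
        for mi, modality in enumerate(config.modalities):
            stage = f"scores[{modality}]"
            t0 = time.time()
            fm = cohort.modality_matrix(modality)
            X = fm.values
            grid = config.grid_for(modality)
            anc = score_anchor_classes(
                X[anchor], y, grid, K1=config.K1, K2=config.K2,
                repetitions=config.repetitions,
                seed=_seed_for(config.seed, 1, mi), modality=modality,
                tol=config.tol,
            )
            hold = score_holdout_group(
                X[anchor], y, X[holdout], grid,
                repetitions=config.repetitions,
                seed=_seed_for(config.seed, 2, mi), K2=config.K2,
                modality=modality, tol=config.tol,
            )
            full = np.full(len(groups), np.nan)
            full[anchor] = anc.scores
            full[holdout] = hold.scores
            full_scores[modality] = full
            results["scores"][modality] = full
            results["performance"][modality] = anc.cv_performance
            prov = np.full(len(groups), "", dtype=object)
            prov[anchor] = anc.provenance
            prov[holdout] = hold.provenance
            for i in range(len(groups)):
                score_rows.append(
                    dict(subject_id=subject_id[i], group=groups[i], modality=modality,
                         score=full[i], provenance=prov[i],
                         repetitions_used=config.repetitions)
                )
            pr = anc.cv_performance.per_repetition.copy()
            pr.insert(0, "modality", modality)
            perf_frames.append(pr)
            fr = anc.cv_performance.fold_records.copy()
            fr.insert(0, "modality", modality)
            fold_frames.append(fr)
            n_conv = int(anc.cv_performance.fold_records.shape[0])
            logger.info("%s done in %.1fs (%d fold models)", stage, time.time() - t0, n_conv)

        stage = "score tables"
        _write_csv(pd.DataFrame(score_rows), "scores.csv")
        _write_csv(pd.concat(perf_frames, ignore_index=True), "performance.csv")
        _write_csv(pd.concat(fold_frames, ignore_index=True), "fold_records.csv")
        oof_rows = []
        for modality in config.modalities:
            oof = results["performance"][modality].oof_probabilities
            anchor_ids = subject_id[anchor]
            for rep in range(oof.shape[1]):
                for s, prob in zip(anchor_ids, oof[:, rep]):
                    oof_rows.append(dict(modality=modality, subject_id=s,
                                         repetition=rep, probability=prob))
        _write_csv(pd.DataFrame(oof_rows), "oof_probabilities.csv")

        stage = "composites"
        comp_df = pd.DataFrame({"subject_id": subject_id, "group": groups})
        anat = composite(full_scores, "anatomical")
        comp = composite(full_scores, "cognitive_anatomical")
        comp_df["anatomical"] = anat
        comp_df["cognitive_anatomical"] = comp
        pts = hypercube_points(full_scores)
        comp_df["risk_zone"] = risk_zones(pts, threshold=config.risk_threshold)
        _write_csv(comp_df, "composites.csv")
        results["composites"] = comp_df

        stage = "maps"
        map_reps = config.map_repetitions or config.repetitions
        results["maps"] = {}
        for mi, modality in enumerate(config.modalities):
            if modality == "cognitive":
                continue
            fm = cohort.modality_matrix(modality)
            ens = weight_ensemble(
                fm.values[anchor], y, repetitions=map_reps,
                grid=config.grid_for(modality),
                seed=_seed_for(config.seed, 3, mi), K2=config.K2, tol=config.tol,
            )
            dmap = stability_ratio(ens, mask=cohort.masks[modality])
            vol = to_volume(dmap, cohort.masks[modality])
            name = f"map_{modality}.nii.gz"
            save_volume(vol, cohort.masks[modality].affine, out / name)
            written.append(name)
            results["maps"][modality] = dmap

        stage = "stratified tables"
        metric_df = pd.DataFrame(
            {m: full_scores[m] for m in config.modalities}
            | {"anatomical": anat, "cognitive_anatomical": comp}
        )
        _write_csv(
            stratified_table(metric_df, groups, strata_order=["CN", "ncMCI", "cMCI", "AD"]).reset_index(),
            "stratified_status.csv",
        )
        age = cohort.subjects["age"].to_numpy(float)
        age_strata = np.where(age < config.age_cutoff, f"<{config.age_cutoff:g}", f">={config.age_cutoff:g}")
        faq = cohort.subjects["faq"].to_numpy(float)
        faq_strata = np.where(faq <= config.faq_cutoff, f"<={config.faq_cutoff:g}", f">{config.faq_cutoff:g}")
        age_tabs, faq_tabs = [], []
        for grp in ("CN", "ncMCI", "cMCI", "AD"):
            sel = groups == grp
            if not sel.any():
                continue
            at = stratified_table(metric_df[sel], age_strata[sel]).reset_index()
            at.insert(0, "group", grp)
            age_tabs.append(at)
            ft = stratified_table(metric_df[sel], faq_strata[sel]).reset_index()
            ft.insert(0, "group", grp)
            faq_tabs.append(ft)
        _write_csv(pd.concat(age_tabs, ignore_index=True), "stratified_age.csv")
        _write_csv(pd.concat(faq_tabs, ignore_index=True), "stratified_faq.csv")

        stage = "survival"
        surv = cohort.survival.set_index("subject_id")
        mci_ids = [s for s in subject_id[holdout] if s in surv.index]
        rec = SurvivalRecords(
            tuple(mci_ids),
            surv.loc[mci_ids, "time_months"].to_numpy(float),
            surv.loc[mci_ids, "event"].to_numpy(int),
        )
        idx = {s: i for i, s in enumerate(subject_id)}
        rows = []
        for metric in metric_df.columns:
            cov = metric_df[metric].to_numpy()[[idx[s] for s in mci_ids]]
            res = cox_fit(cov, rec)
            rows.append(
                dict(metric=metric, hazard_ratio_per_sd=res.hazard_ratio,
                     ci95_low=res.ci95_low, ci95_high=res.ci95_high,
                     z_statistic=res.z_statistic, p_value=res.p_value,
                     n=res.n, n_events=res.n_events)
            )
        surv_df = pd.DataFrame(rows)
        _write_csv(surv_df, "survival_results.csv")
        results["survival"] = surv_df

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "files": {name: _sha256(out / name) for name in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        results["manifest"] = manifest
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed ({err}); completed outputs kept in {out}"
        ) from err
    return results
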