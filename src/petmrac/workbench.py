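"""End-to-end experiments: baseline cohort plus the four outlier scenarios.

For each evaluation subject a phantom is generated, optionally corrupted
(truncation, metal, single lung, lung nodule), its MR is conditioned (N4,
optional histogram matching to a cohort reference, unit-range normalization),
three
synthetic CTs are built (segmentation, multi-atlas, deep learning), PET data
are simulated from the truth activity with the reference-CT attenuation, and
four reconstruction arms (reference + three candidates) are compared in SUV.

Seeds derive hierarchically from ``master_seed`` (training cohort, atlas
cohort, evaluation subjects, Poisson noise) so any stage is replayable in
isolation.  DL training subjects and atlas members are disjoint from the
evaluation subjects (subject-level cross-validation / leave-one-out).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, pet, phantom, preprocess, seg
from .atlas import AtlasSCT
from .dl import DeepSCT

log = logging.getLogger(__name__)

SCENARIOS = ("baseline", "truncation", "metal", "single_lung", "nodule")
ARMS = ("seg", "atlas", "dl")


@dataclass
class ExperimentConfig:
    scenario: str = "baseline"
    n_subjects: int = 3
    n_atlases: int = 4
    n_train_subjects: int = 16
    train_slices_per_subject: int = 4
    master_seed: int = 0
    # phantom geometry (None -> desk preset; nodule scenario needs a stack)
    phantom_config: phantom.PhantomConfig = None
    # conditioning: N4 always; histogram matching to a cohort reference is
    # opt-in (phantom cohorts share one simulated intensity calibration, and
    # percentile unit-range normalization is composition-robust)
    bias_correct: bool = True
    match_reference: bool = False
    # DL
    dl_epochs: int = 10
    dl_batch: int = 8
    # reconstruction
    n_angles: int = 176
    osem_iterations: int = 4
    osem_subsets: int = 8
    total_counts: object = 5e5  # per slice; "noiseless" for deterministic runs
    suv_floor: float = evaluation.SUV_FLOOR
    # scenario parameters (desk-phantom coordinates, mm)
    truncation_fraction: float = 0.15
    metal_center: tuple = (58.0, -32.0)
    metal_void_radius: float = 28.0
    metal_implant_radius: float = 9.0
    lung_side: str = "left"
    nodule_center: tuple = (34.0, -12.0, 0.0)
    nodule_radius: float = 7.0
    nodule_uptake: float = 4.0

    def resolved_phantom_config(self) -> phantom.PhantomConfig:
        if self.phantom_config is not None:
            return self.phantom_config
        if self.scenario == "nodule":
            return phantom.desk_config(n_slices=5, slice_thickness=4.0)
        return phantom.desk_config(n_slices=1)

    def seeds(self):
        base = int(self.master_seed) * 100000
        return {
            "train": [base + 300 + i for i in range(self.n_train_subjects)],
            "atlas": [base + 200 + i for i in range(self.n_atlases)],
            "eval": [base + 100 + i for i in range(self.n_subjects)],
            "poisson": [base + 400 + i for i in range(self.n_subjects)],
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _condition_mr(mr, body_hint, spacing, reference_mr, bias_correct=True):
    """N4 + histogram matching + [0, 1] normalization."""
    out = np.asarray(mr, np.float32)
    if bias_correct:
        mask = body_hint if body_hint is not None else np.ones(out.shape, bool)
        out = preprocess.correct_bias_field(out, mask, spacing)
    if reference_mr is not None:
        out = preprocess.match_histogram(out, reference_mr)
    return preprocess.normalize_unit_range(out)


def _rough_body(mr):
    """Cheap foreground hint for N4 (threshold at the intensity midpoint)."""
    thr = 0.5 * (float(np.percentile(mr, 1)) + float(np.percentile(mr, 99)))
    return mr > min(thr, float(np.percentile(mr, 60)))


def build_training_cohort(cfg: ExperimentConfig):
    """Uncorrupted training phantoms -> conditioned MR and CT slice stacks."""
    pconf = cfg.resolved_phantom_config()
    stack_conf = dataclasses.replace(
        pconf, grid_shape=(cfg.train_slices_per_subject,) + pconf.grid_shape[1:])
    seeds = cfg.seeds()["train"]
    phantoms = [phantom.generate_phantom(stack_conf, s) for s in seeds]
    reference_mr = phantoms[0].mr if cfg.match_reference else None
    mrs, cts = [], []
    for ph in phantoms:
        mrs.append(_condition_mr(ph.mr, _rough_body(ph.mr), ph.spacing,
                                 reference_mr, cfg.bias_correct))
        cts.append(ph.ct_hu)
    return mrs, cts, reference_mr


def train_dl_model(cfg: ExperimentConfig):
    mrs, cts, reference_mr = build_training_cohort(cfg)
    est = DeepSCT(network="desk", epochs=cfg.dl_epochs, batch_slices=cfg.dl_batch,
                  seed=cfg.master_seed)
    est.fit(mrs, cts)
    return est, reference_mr


def build_atlas_model(cfg: ExperimentConfig, reference_mr):
    pconf = cfg.resolved_phantom_config()
    seeds = cfg.seeds()["atlas"]
    mrs, cts, ids = [], [], []
    for s in seeds:
        ph = phantom.generate_phantom(pconf, s)
        mrs.append(_condition_mr(ph.mr, _rough_body(ph.mr), ph.spacing,
                                 reference_mr, cfg.bias_correct))
        cts.append(ph.ct_hu)
        ids.append(f"atlas_{s}")
    est = AtlasSCT()
    est.fit(mrs, cts, spacing=pconf.voxel_spacing, subject_ids=ids)
    return est


def apply_scenario(ph: phantom.TorsoPhantom, cfg: ExperimentConfig):
    """Corrupt a phantom per the configured scenario; returns (phantom, affected)."""
    if cfg.scenario == "baseline":
        return ph, None
    if cfg.scenario == "truncation":
        out = phantom.inject_truncation(ph, cfg.truncation_fraction)
        return out, out.organs["truncation_affected"]
    if cfg.scenario == "metal":
        out = phantom.inject_metal(ph, cfg.metal_center, cfg.metal_void_radius,
                                   cfg.metal_implant_radius)
        return out, out.organs["metal_affected"]
    if cfg.scenario == "single_lung":
        out = phantom.remove_lung(ph, cfg.lung_side)
        core = out.organs[f"removed_{cfg.lung_side}_lung"]
        from scipy import ndimage
        band = ndimage.binary_dilation(core, seg._plane_ball(2, core.ndim))
        return out, band & out.body_mask
    if cfg.scenario == "nodule":
        out = phantom.add_lung_nodule(ph, cfg.nodule_center, cfg.nodule_radius,
                                      cfg.nodule_uptake)
        return out, out.organs["lesion_1"]
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def _reconstruct_arms(ph, mu_maps, cfg, poisson_seed):
    geom = pet.make_geometry(ph.ct_hu.shape, ph.spacing[-2:], cfg.n_angles)
    mu_ref = mu_maps["reference_ct"]
    sino = pet.forward_project(ph.activity, mu_ref, geom,
                               total_counts=cfg.total_counts, seed=poisson_seed)
    recons = {}
    for arm, mu in mu_maps.items():
        recons[arm] = pet.osem_reconstruct(sino, mu, cfg.osem_iterations,
                                           cfg.osem_subsets)
    return pet.suv_normalize(recons, ph.body_mask)


def run_subject(cfg: ExperimentConfig, subject_seed, poisson_seed, dl_est,
                atlas_est, reference_mr, keep_maps=False):
    pconf = cfg.resolved_phantom_config()
    ph = phantom.generate_phantom(pconf, subject_seed)
    ph, affected = apply_scenario(ph, cfg)
    spacing = ph.spacing

    mr_norm = _condition_mr(ph.mr, _rough_body(ph.mr), spacing, reference_mr,
                            cfg.bias_correct)

    _, seg_sct, seg_mu = seg.build_seg_sct(mr_norm, spacing=spacing)
    atlas_sct = atlas_est.predict(mr_norm)
    dl_sct = dl_est.predict(mr_norm)

    mu_maps = {
        "reference_ct": pet.hu_to_mu(ph.ct_hu, spacing, "reference_ct"),
        "seg": pet.AttenuationMap(mu=seg_mu.mu, spacing=spacing, source="seg"),
        "atlas": pet.hu_to_mu(atlas_sct, spacing, "atlas"),
        "dl": pet.hu_to_mu(dl_sct, spacing, "dl"),
    }
    suvs = _reconstruct_arms(ph, mu_maps, cfg, poisson_seed)

    truth_lungs = np.zeros(ph.labels.shape, bool)
    for key in ("right_lung", "left_lung"):
        if key in ph.organs:
            truth_lungs |= ph.organs[key]
    masks = evaluation.tissue_masks_from_ct(ph.ct_hu, truth_lungs, ph.body_mask)

    result = {"subject": f"s{subject_seed}", "tissue": {}, "organs": {},
              "lesions": {}, "rmse": {}, "scts": {"seg": seg_sct,
                                                  "atlas": atlas_sct,
                                                  "dl": dl_sct}}
    lesion_masks = {k: v for k, v in ph.organs.items() if k.startswith("lesion_")}
    for arm in ARMS:
        bias, valid = evaluation.voxel_bias_map(suvs[arm], suvs["reference_ct"],
                                                cfg.suv_floor)
        result["tissue"][arm] = {
            "lung": evaluation.region_stats(bias, valid, masks.lung),
            "soft": evaluation.region_stats(bias, valid, masks.soft),
            "bone": evaluation.region_stats(bias, valid, masks.bone),
        }
        organs = {}
        for organ in ("right_lung", "left_lung", "liver_like", "spine"):
            if organ in ph.organs:
                organs[organ] = evaluation.region_stats(bias, valid,
                                                        ph.organs[organ])
        if affected is not None:
            organs["affected"] = evaluation.region_stats(bias, valid, affected)
        result["organs"][arm] = organs
        if lesion_masks:
            result["lesions"][arm] = evaluation.voi_bias(
                bias, valid, lesion_masks, ph.voxel_volume_ml, suv=suvs[arm])
        result["rmse"][arm] = evaluation.rmse(suvs[arm], suvs["reference_ct"],
                                              masks.body)
        if keep_maps:
            result.setdefault("bias", {})[arm] = bias
            result.setdefault("valid", {})[arm] = valid
    if keep_maps:
        result["phantom"] = ph
        result["affected"] = affected
        result["suv"] = suvs
    return result


def run_experiment(cfg: ExperimentConfig, dl_est=None, atlas_est=None,
                   reference_mr=None, outdir=None, keep_maps=False):
    """Run one scenario end to end; returns ``(BiasReport, per_subject_list)``.

    A failing subject is recorded and skipped, the run continues.  Pre-trained
    DL/atlas estimators may be passed in so several scenarios share one
    training cohort (the training subjects never overlap evaluation seeds).
    """
    if cfg.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    if dl_est is None:
        dl_est, reference_mr = train_dl_model(cfg)
    if atlas_est is None:
        atlas_est = build_atlas_model(cfg, reference_mr)
    seeds = cfg.seeds()
    per_subject, errors = [], []
    for s_seed, p_seed in zip(seeds["eval"], seeds["poisson"]):
        try:
            per_subject.append(
                run_subject(cfg, s_seed, p_seed, dl_est, atlas_est,
                            reference_mr, keep_maps=keep_maps))
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.exception("subject seed %s failed", s_seed)
            errors.append({"subject_seed": s_seed, "error": repr(exc)})
    report = evaluation.build_report(per_subject)
    report.meta = {"scenario": cfg.scenario, "master_seed": cfg.master_seed,
                   "n_subjects": cfg.n_subjects, "errors": errors}
    if outdir is not None:
        _save_artifacts(Path(outdir), cfg, report, per_subject)
    return report, per_subject


def affected_region_bias(per_subject, arm):
    """Mean of the per-subject affected-region mean bias for one arm (%)."""
    vals = [s["organs"][arm]["affected"].mean for s in per_subject
            if "affected" in s.get("organs", {}).get(arm, {})]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError("no affected-region statistics available")
    return float(np.mean(vals))


def _save_artifacts(outdir, cfg, report, per_subject):
    from . import io
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir)
    (outdir / "report.md").write_text(report.to_markdown())
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict.pop("phantom_config", None)
    io.write_yaml(outdir / "experiment.yaml", cfg_dict)
    cfg.resolved_phantom_config().to_yaml(outdir / "phantom.yaml")
    spacing = cfg.resolved_phantom_config().voxel_spacing
    for subj in per_subject:
        d = outdir / subj["subject"]
        d.mkdir(exist_ok=True)
        for arm, sct in subj.get("scts", {}).items():
            io.write_volume(d / f"sct_{arm}.nii.gz", sct, spacing, np.float32)


def make_fixtures(seed: int, directory, n_subjects: int = 8):
    """Deterministic mini-cohort of desk phantoms written as NIfTI bundles."""
    directory = Path(directory)
    conf = phantom.desk_config(n_slices=1)
    conf = dataclasses.replace(conf, noise_seed=int(seed))
    for i in range(n_subjects):
        ph = phantom.generate_phantom(conf, i)
        ph.save(directory / f"subject_{i:02d}")
    return directory
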