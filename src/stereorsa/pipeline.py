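"""End-to-end pipeline: simulate, analyze every stage, write a report.

``run_all`` generates a full synthetic study with known ground truth and
pushes it through the complete analysis chain:

  simulate → trajectories/MD → subjective DMs → stereotype scores →
  deviation GEE + d′ → GLM patterns → ROI RSA (both masking arms) →
  searchlight + permutation → PPI → connectivity–representation link

The planted structure couples the stages the way the scientific
hypothesis does: each subject's neural patterns in the unmasked arm
realize that subject's own subjective DM (weight w_i), the masked arm
carries none of it (weight 0), and the subject's PPI coupling scales
with the same w_i — so connectivity disruption predicts
representational disruption across subjects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, glm, mousetracking as mt, ppi, rsa, searchlight, stereotype
from .core import DissimilarityMatrix
from .synthetic import (DesignSpec, GroundTruth, SignalRegion,
                        gen_bold_session, gen_bold_voxels, gen_discrimination,
                        gen_patterns, gen_ratings, gen_trajectories,
                        gen_volume_dataset, make_schedule)

log = logging.getLogger("stereorsa.pipeline")


@dataclass
class PipelineConfig:
    """Desk-scale defaults; every random stage draws from ``seed``."""

    seed: int = 0
    n_subjects: int = 24
    n_faces_per_cell: int = 35
    n_null_events: int = 77
    tr: float = 2.0
    n_runs: int = 4
    # planted truth
    stereotype_bias_mean: float = 0.49
    stereotype_bias_sd: float = 0.62
    md_baseline: float = 0.40
    congruency_effect: float = 0.075
    moderation: float = 0.0285
    ppi_coupling: float = 0.3
    noise_sds: dict = field(default_factory=lambda: {
        "md": 0.5, "md_subject": 0.08, "ratings": 0.3, "pattern": 0.3,
        "bold": 0.1})
    # analysis parameters
    n_bins: int = 100
    n_voxels_roi: int = 600
    glm_noise_sd: float = 0.5
    searchlight_radius: float = 3.0
    grid_dim: int = 12
    signal_radius: float = 4.0
    fwhm_mm: float = 6.0
    voxel_size_mm: float = 2.0
    n_perm: int = 300
    ridge: float = 1.0e-3
    hrf_shape: float = 8.6
    hrf_scale: float = 0.547
    out_dir: str = "results"

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("pipeline needs at least 3 subjects")
        if self.n_perm < 1 or self.grid_dim < 2 * int(self.searchlight_radius) + 1:
            raise ValueError("invalid searchlight configuration")
        DesignSpec(n_subjects=self.n_subjects,
                   n_faces_per_cell=self.n_faces_per_cell,
                   n_null_events=self.n_null_events, tr=self.tr,
                   n_runs=self.n_runs, seed=self.seed)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _safe_group_rho(rhos) -> dict:
    """Mean rho plus the Fisher-z group test; t/p are null when the rhos
    are constant across subjects (degenerate t)."""
    out = {"mean_rho": float(np.mean(rhos))}
    try:
        gt = rsa.group_test(rhos, "fisher_z")
        out.update(t=gt.t, p=gt.p)
    except ValueError:
        out.update(t=None, p=None)
    return out


def _interpret(planted: float, estimate: float, p: float) -> str:
    if planted == 0:
        return "null as expected" if p >= 0.05 else "false positive"
    if p < 0.05 and np.sign(estimate) == np.sign(planted):
        return "recovered"
    return "not recovered"


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the results bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("ratings", "trajectories", "discrimination", "patterns",
         "bold", "volumes", "schedule", "subject_weights"),
        ss.spawn(8))}
    truth = GroundTruth(
        stereotype_bias_mean=config.stereotype_bias_mean,
        stereotype_bias_sd=config.stereotype_bias_sd,
        md_baseline=config.md_baseline,
        congruency_effect=config.congruency_effect,
        moderation=config.moderation,
        ppi_coupling=config.ppi_coupling,
        noise_sds=dict(config.noise_sds),
    )
    spec = DesignSpec(n_subjects=config.n_subjects,
                      n_faces_per_cell=config.n_faces_per_cell,
                      n_null_events=config.n_null_events,
                      tr=config.tr, n_runs=config.n_runs, seed=config.seed)
    hrf = glm.HrfParams(shape=config.hrf_shape, scale=config.hrf_scale)
    results: dict = {
        "config": asdict(config),
        "design_echo": {
            "n_faces": spec.n_faces,
            "mousetracking_trials_per_subject": 2 * spec.n_faces,
            "rating_trials_per_subject": 4 * 30,
            "trial_duration_ms": spec.trial_duration_ms,
        },
    }

    # --- behavioral simulation ------------------------------------------
    log.info("stage ratings/stereotype: n_subjects=%d", config.n_subjects)
    ratings, planted_bias = gen_ratings(
        config.n_subjects, truth.stereotype_bias_mean,
        truth.stereotype_bias_sd, truth.noise_sds["ratings"],
        seed=seeds["ratings"])
    scores = stereotype.scores_table(ratings)
    score_by_subject = scores.set_index("subject")["score"]
    results["stereotype"] = {
        "planted_mean": float(planted_bias.mean()),
        "recovered_mean": float(score_by_subject.mean()),
        "recovered_sd": float(score_by_subject.std(ddof=1)),
    }

    log.info("stage mousetracking")
    trial_set = gen_trajectories(planted_bias, truth,
                                 n_faces_per_cell=config.n_faces_per_cell,
                                 seed=seeds["trajectories"])
    metrics = mt.metrics_table(trial_set.t_ms, trial_set.xy,
                               trial_set.trials["response_side"].to_numpy(),
                               n_bins=config.n_bins)
    trials = trial_set.trials.join(metrics)
    retained, exclusion = mt.exclude_trials(trials)
    results["exclusion"] = exclusion

    retained = retained.assign(
        stereotype=score_by_subject.loc[retained["subject"]].to_numpy())
    fit = behavior.fit_md_model(retained, value_col="md")
    slopes = behavior.simple_slopes(fit)
    ge = fit.term("gender:emotion")
    ges = fit.term("gender:emotion:stereotype")
    results["md_model"] = {
        "planted_gender_emotion_B": -2.0 * truth.congruency_effect,
        "gender_emotion": {k: float(ge[k]) for k in ge.index},
        "planted_three_way_B": -2.0 * truth.moderation,
        "three_way": {k: float(ges[k]) for k in ges.index},
        "simple_slopes": {lvl: {k: float(v) for k, v in row.items()}
                          for lvl, row in slopes.iterrows()},
        "interpretation": _interpret(-2.0 * truth.congruency_effect,
                                     float(ge["B"]), float(ge["p"])),
    }

    dms, group_dm = mt.subject_dms(retained)
    subjects = sorted(dms)

    log.info("stage discrimination")
    responses, planted_d = gen_discrimination(
        config.n_subjects, config.n_faces_per_cell,
        seed=seeds["discrimination"])
    dtable = behavior.dprime_table(responses)
    results["discrimination"] = {
        "planted_mean_dprime": float(planted_d.mean()),
        "recovered_mean_dprime": float(dtable["d_prime"].mean()),
        "n_excluded": int(dtable["excluded"].sum()),
    }

    # --- neural simulation + ROI RSA ------------------------------------
    log.info("stage glm/rsa: %d voxels per ROI", config.n_voxels_roi)
    # per-subject latent: how strongly this subject's own subjective DM is
    # expressed in the unmasked arm AND how strong their seed-target
    # coupling modulation is -- the common cause behind the link stage
    weights = seeds["subject_weights"].uniform(0.0, 1.0, config.n_subjects)
    arm_betas = {"unmasked": [], "masked": []}
    arm_rhos = {"unmasked": [], "masked": []}
    congr = stereotype.congruency_dm()
    schedule = make_schedule(spec, rng=seeds["schedule"])
    valid = np.ones(len(subjects), dtype=bool)
    for si, subj in enumerate(subjects):
        subj_dm = dms[subj]
        for arm, w in (("unmasked", float(weights[si])), ("masked", 0.0)):
            target = subj_dm.blend(group_dm, w) if w > 0 else group_dm
            runs = schedule[schedule["masking"] == arm]["run"].unique()
            t_maps = []
            for r in runs:
                pats = gen_patterns(target, config.n_voxels_roi,
                                    truth.noise_sds["pattern"],
                                    seed=seeds["patterns"])
                bold = gen_bold_voxels(schedule, pats, hrf=hrf,
                                       noise_sd=config.glm_noise_sd,
                                       seed=seeds["bold"], tr=config.tr,
                                       run=r)
                run_sched = schedule[schedule["run"] == r]
                design = glm.build_design(run_sched, bold.shape[0],
                                          tr=config.tr, hrf=hrf)
                _, t = glm.fit_glm(bold, design)
                t_maps.append(t)
            pattern_set = glm.condition_patterns(t_maps)
            ndm = rsa.neural_dm(pattern_set.data)
            try:
                beta = rsa.regression_rsa(ndm, subj_dm, [group_dm])
            except ValueError:
                # subject's DM rank-ties with the group DM: partial beta
                # not identified for this subject; drop from group stats
                valid[si] = False
                beta = np.nan
            arm_betas[arm].append(beta)
            arm_rhos[arm].append(rsa.spearman_rsa(ndm, congr).rho)
    unmasked_beta = np.array(arm_betas["unmasked"])[valid]
    masked_beta = np.array(arm_betas["masked"])[valid]
    gt_u = rsa.group_test(unmasked_beta)
    gt_m = rsa.group_test(masked_beta)
    contrast = rsa.paired_contrast(unmasked_beta, masked_beta)
    results["roi_rsa"] = {
        "n_subjects_used": int(valid.sum()),
        "unmasked": {"mean_beta": gt_u.mean, "t": gt_u.t, "df": gt_u.df, "p": gt_u.p},
        "masked": {"mean_beta": gt_m.mean, "t": gt_m.t, "df": gt_m.df, "p": gt_m.p},
        "contrast": {"t": contrast.t, "df": contrast.df, "p": contrast.p},
        "congruency_rho": {arm: _safe_group_rho(arm_rhos[arm])
                           for arm in ("unmasked", "masked")},
        "interpretation": _interpret(1.0 if any(weights) else 0.0,
                                     gt_u.mean, gt_u.p),
    }

    # --- searchlight -----------------------------------------------------
    log.info("stage searchlight: grid %d^3, radius %.0f, %d permutations",
             config.grid_dim, config.searchlight_radius, config.n_perm)
    grid = (config.grid_dim,) * 3
    center = tuple(d // 2 for d in grid)
    region = SignalRegion(center=center, radius=config.signal_radius)
    subject_targets = [dms[s].blend(group_dm, float(w))
                       for s, w in zip(subjects, weights)]
    vols = gen_volume_dataset(grid, [region], subject_targets,
                              noise_sd=1.0,
                              signal_noise_sd=truth.noise_sds["pattern"],
                              seed=seeds["volumes"])
    maps = []
    for si, subj in enumerate(subjects):
        if not valid[si]:     # partial beta unidentified for this subject
            continue
        m = searchlight.run_searchlight(vols.volumes[si], vols.mask,
                                        dms[subj], [group_dm],
                                        radius=config.searchlight_radius)
        maps.append(searchlight.smooth_map(m, config.fwhm_mm,
                                           config.voxel_size_mm))
    perm = searchlight.group_permutation(maps, n_perm=config.n_perm,
                                         seed=config.seed)
    sig = perm["p_corrected"] < 0.05
    inside = vols.region_labels > 0
    results["searchlight"] = {
        "n_significant": int(np.nansum(sig)),
        "n_significant_inside_region": int(np.nansum(sig & inside)),
        "frac_region_significant": float(sig[inside].mean()),
        "critical_t": perm["critical_t"],
    }

    # --- PPI + link ------------------------------------------------------
    log.info("stage ppi/link")
    ppi_betas = []
    for si, subj in enumerate(subjects):
        subj_truth = GroundTruth(
            stereotype_bias_mean=truth.stereotype_bias_mean,
            stereotype_bias_sd=truth.stereotype_bias_sd,
            ppi_coupling=truth.ppi_coupling * float(weights[si]),
            noise_sds=truth.noise_sds)
        session = gen_bold_session(schedule, subj_truth, hrf=hrf,
                                   seed=seeds["bold"], tr=config.tr)
        design = ppi.build_ppi_design(session.seed_bold, session.condition,
                                      hrf=hrf, tr=config.tr,
                                      ridge=config.ridge, run=session.run)
        ppi_betas.append(ppi.fit_ppi(session.target_bold, design)
                         .beta_interaction)
    ppi_betas = np.array(ppi_betas)
    gtest = ppi.group_ppi_test(ppi_betas)
    link = ppi.link_connectivity_representation(
        ppi_betas[valid], unmasked_beta - masked_beta)
    results["ppi"] = {
        "planted_mean_coupling": float(truth.ppi_coupling * weights.mean()),
        "mean_interaction_beta": gtest.mean, "t": gtest.t, "p": gtest.p,
        "interpretation": _interpret(truth.ppi_coupling, gtest.mean, gtest.p),
    }
    results["link"] = {
        "r": link.r, "p_one_tailed": link.p_one_tailed, "n": link.n,
        "interpretation": _interpret(
            truth.ppi_coupling, link.r,
            link.p_one_tailed if truth.ppi_coupling else 2 * link.p_one_tailed),
    }

    # --- outputs ---------------------------------------------------------
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    _write_summary(out_dir / "summary.txt", results)
    log.info("wrote %s", out_dir / "results.json")
    return results


def _write_summary(path, res: dict) -> None:
    echo = res["design_echo"]
    md = res["md_model"]
    roi = res["roi_rsa"]
    lines = [
        "stereorsa pipeline summary",
        "==========================",
        f"design: {echo['n_faces']} faces, "
        f"{echo['mousetracking_trials_per_subject']} mouse-tracking trials, "
        f"{echo['rating_trials_per_subject']} rating trials, "
        f"{echo['trial_duration_ms']} ms trials",
        f"stereotype score: planted mean {res['stereotype']['planted_mean']:.3f}, "
        f"recovered {res['stereotype']['recovered_mean']:.3f}",
        f"gender x emotion B = {md['gender_emotion']['B']:.4f} "
        f"(planted {md['planted_gender_emotion_B']:.4f}) "
        f"[{md['interpretation']}]",
        f"ROI RSA beta: unmasked {roi['unmasked']['mean_beta']:.3f} "
        f"(p={roi['unmasked']['p']:.4f}), masked {roi['masked']['mean_beta']:.3f} "
        f"(p={roi['masked']['p']:.4f}) [{roi['interpretation']}]",
        f"searchlight: {res['searchlight']['n_significant']} significant voxels, "
        f"{res['searchlight']['n_significant_inside_region']} inside the planted region",
        f"PPI interaction beta {res['ppi']['mean_interaction_beta']:.3f} "
        f"(p={res['ppi']['p']:.4f}) [{res['ppi']['interpretation']}]",
        f"connectivity-representation link r = {res['link']['r']:.3f}, "
        f"one-tailed p = {res['link']['p_one_tailed']:.4f} "
        f"[{res['link']['interpretation']}]",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
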