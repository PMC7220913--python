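"""End-to-end orchestration: train on session 1, validate on retest sessions,
generalize consensus features to an external cohort.

Every run writes a manifest (config hash, seeds, package version) so results
are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .config import RunConfig
from .cpm import (FeatureMask, apply_model, consensus_features,
                  fit_consensus_model, kfold_cv, loocv)
from .stats import permutation_test
from .synth import SyntheticSpec, generate_cohort, generate_external, generate_retest

logger = logging.getLogger(__name__)

__all__ = ["load_or_generate", "run_internal", "run_external"]


def _manifest(config: RunConfig) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def load_or_generate(config: RunConfig):
    """Return (time1, time2, time3, external) cohorts plus ground truth.

    If ``config.input_dir`` is set, cohorts are read from
    ``<input_dir>/{time1,time2,time3,external}``; missing retest/external
    directories yield ``None``.  Otherwise a synthetic study is generated.
    """
    if config.input_dir:
        base = Path(config.input_dir)
        t1_dir = base / "time1"
        if not (t1_dir / "participants.csv").exists():
            raise FileNotFoundError(f"missing training cohort: {t1_dir}/participants.csv")
        cohorts = []
        for name in ("time1", "time2", "time3", "external"):
            d = base / name
            cohorts.append(Cohort.read(d, n_nodes=config.n_nodes)
                           if (d / "participants.csv").exists() else None)
        return (*cohorts, None)

    s = config.synth
    spec = SyntheticSpec(
        n_participants=s.n_participants, n_nodes=s.n_nodes,
        n_pos_edges=s.n_pos_edges, n_neg_edges=s.n_neg_edges,
        effect_r=s.effect_r, gf_mean=s.gf_mean, gf_sd=s.gf_sd,
        retest_reliability=s.retest_reliability_t2,
        external_scale=s.external_scale, external_offset=s.external_offset,
        external_noise_sd=s.external_noise_sd,
        fd_spike_rate=s.fd_spike_rate, seed=config.seed,
    )
    t1, truth = generate_cohort(spec)
    t2 = generate_retest(t1, truth, s.retest_reliability_t2, seed=config.seed + 1,
                         session="time2")
    t3 = generate_retest(t1, truth, s.retest_reliability_t3, seed=config.seed + 2,
                         session="time3")
    external = generate_external(spec, truth, seed=config.seed + 3)
    return t1, t2, t3, external, truth


def _write_predictions(out: Path, name: str, result) -> None:
    pd.DataFrame({"observed": result.observed, "predicted": result.predicted}) \
        .to_csv(out / f"predictions_{name}.csv", index=False)


def run_internal(config: RunConfig) -> dict:
    """Internal validation: LOOCV on session 1, per-fold models scored on
    retest sessions, repeated k-fold, optional permutation test."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, t2, t3, _external, _truth = load_or_generate(config)

    summary: dict = _manifest(config)
    result_t1 = loocv(t1, p_threshold=config.selection_p, variant=config.variant,
                      alpha_motion=config.alpha_motion)
    _write_predictions(out, "time1", result_t1)
    summary["time1"] = {"r": result_t1.r_pred_obs, "p_parametric": result_t1.p_parametric,
                        "n": int(t1.n_participants)}

    consensus = consensus_features(result_t1.fold_masks)
    (out / "consensus_mask.json").write_text(json.dumps(consensus.to_dict(), indent=2))
    (out / "fold_masks.json").write_text(
        json.dumps([m.to_dict() for m in result_t1.fold_masks])
    )

    for name, session in (("time2", t2), ("time3", t3)):
        if session is None:
            continue
        result = loocv(t1, p_threshold=config.selection_p, variant=config.variant,
                       alpha_motion=config.alpha_motion, test_cohort=session)
        _write_predictions(out, name, result)
        summary[name] = {"r": result.r_pred_obs, "p_parametric": result.p_parametric,
                         "n": int(session.n_participants)}

    r_values, (r_mean, r_sd) = kfold_cv(
        t1, k=min(config.kfold_k, t1.n_participants), repeats=config.kfold_repeats,
        seed=config.seed, p_threshold=config.selection_p, variant=config.variant,
        alpha_motion=config.alpha_motion,
    )
    summary["kfold"] = {"k": min(config.kfold_k, t1.n_participants),
                        "repeats": config.kfold_repeats,
                        "r_mean": r_mean, "r_sd": r_sd,
                        "r_values": r_values.tolist()}

    if config.run_permutation:
        perm = permutation_test(t1, B=config.permutations, seed=config.seed,
                                p_threshold=config.selection_p, variant=config.variant,
                                alpha_motion=config.alpha_motion)
        summary["permutation"] = {"p": perm.p_permutation, "B": perm.B,
                                  "observed_r": perm.observed_r}

    logger.info("internal run: time1 r=%.3f over %d participants",
                result_t1.r_pred_obs, t1.n_participants)
    (out / "summary_internal.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_external(config: RunConfig) -> dict:
    """External validation: consensus features from session-1 LOOCV, one model
    fitted on the full training cohort, applied to the external cohort."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, _t2, _t3, external, _truth = load_or_generate(config)
    if external is None:
        raise FileNotFoundError("no external cohort available")
    if external.n_edges != t1.n_edges:
        raise ValueError("edge order/count mismatch between training and external cohorts")

    result_t1 = loocv(t1, p_threshold=config.selection_p, variant=config.variant,
                      alpha_motion=config.alpha_motion)
    consensus = consensus_features(result_t1.fold_masks)
    if consensus.is_empty:
        raise RuntimeError("empty consensus feature set; external validation impossible")
    model = fit_consensus_model(t1, consensus, variant=config.variant)
    result = apply_model(model, external)

    summary = _manifest(config)
    summary["external"] = {"r": result.r_pred_obs, "p_parametric": result.p_parametric,
                           "n": int(external.n_participants),
                           "n_consensus_pos": int(consensus.positive_edges.size),
                           "n_consensus_neg": int(consensus.negative_edges.size)}
    _write_predictions(out, "external", result)
    (out / "consensus_mask.json").write_text(json.dumps(consensus.to_dict(), indent=2))
    (out / "summary_external.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
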