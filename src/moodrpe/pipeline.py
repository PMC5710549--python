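"""End-to-end reproducible pipeline: simulate → fit → compare → stats.

Every stage writes tab-separated text with fixed float formatting, so a
rerun with the same config (including its seed) reproduces byte-identical
tabular outputs; a JSON manifest records the config snapshot, seeds,
package version, and per-file digests.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from .cohort import ChoiceParams, Cohort, CohortConfig, generate_cohort
from .fitting import MODEL_SPECS, FitResult, compare_models, fit_mood_model
from .io import write_config, write_manifest, write_session
from .stats import apply_exclusion, ranksum_test, residualized_spearman, spearman

__all__ = ["config_from_dict", "config_to_dict", "replicate", "fit_cohort", "stats_table"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"

_TUPLE_FIELDS = {"hamd_mdd", "hamd_control", "phq_mdd", "phq_control", "gamma_range"}


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain mapping (e.g. a YAML config).

    Recognises every CohortConfig field plus ``n`` as an alias for the
    smartphone cohort size.
    """
    d = dict(d)
    variant = d.pop("variant", "lab")
    if "n" in d:
        d["n_mdd"] = int(d.pop("n"))
        d.setdefault("n_control", 0)
    choice = d.pop("choice", None)
    for key in _TUPLE_FIELDS & d.keys():
        d[key] = tuple(d[key])
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = CohortConfig(variant=variant, **d)
    if choice is not None:
        cfg.choice = ChoiceParams(**choice)
    if variant == "smartphone" and "money_scale" not in d:
        cfg.money_scale = 80.0
    return cfg


def config_to_dict(cfg: CohortConfig) -> dict:
    out = dataclasses.asdict(cfg)
    for key in _TUPLE_FIELDS:
        out[key] = list(out[key])
    return out


def fit_cohort(
    cohort: Cohort, spec_ids: tuple[str, ...] = ("full", "no_expectation", "split_rpe")
) -> dict[str, dict[str, FitResult]]:
    """Fit every participant under every requested model spec."""
    fits: dict[str, dict[str, FitResult]] = {}
    for p in cohort.participants:
        if p.ratings is None:
            continue
        fits[p.id] = {
            sid: fit_mood_model(p.session, p.ratings, MODEL_SPECS[sid])
            for sid in spec_ids
        }
    return fits


def fits_frame(fits: dict[str, dict[str, FitResult]]) -> pd.DataFrame:
    rows = []
    for pid in sorted(fits):
        for sid in sorted(fits[pid]):
            f = fits[pid][sid]
            pr = f.params
            rows.append(
                {
                    "id": pid, "spec": sid,
                    "w0": pr.w0, "gamma": pr.gamma, "w_cr": pr.w_cr,
                    "w_ev": pr.w_ev, "w_rpe": pr.w_rpe,
                    "w_r": pr.w_r, "w_negev": pr.w_negev,
                    "r2": f.r2, "sse": f.sse, "n_probes": f.n_probes,
                    "k_params": f.k_params, "ic": f.ic,
                    "degenerate": int(f.degenerate),
                }
            )
    return pd.DataFrame(rows)


def _covariate_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Sex, university-degree indicator, and age — the covariates removed
    in residualized correlations."""
    return pd.DataFrame(
        {
            "sex": (meta["sex"] == "F").astype(float),
            "degree": meta["degree"].astype(float),
            "age": meta["age"].astype(float),
        },
        index=meta.index,
    )


def stats_table(meta: pd.DataFrame, fit_df: pd.DataFrame) -> pd.DataFrame:
    """The group-level analysis table for one cohort.

    Rows: group difference in symptom severity (rank sum); Spearman and
    covariate-residualized Spearman correlations of the fitted baseline
    mood (w0), RPE weight, and forgetting factor with symptom severity;
    group rank-sum comparisons of each fitted weight and of r².
    """
    full = fit_df[fit_df["spec"] == "full"].set_index("id")
    meta = meta.set_index("id").loc[full.index].reset_index()
    full = full.reset_index()
    symptom = meta["hamd"].where(meta["hamd"].notna(), meta["bdi"]).to_numpy(float)
    is_mdd = (meta["group"] == "MDD").to_numpy()
    cov = _covariate_table(meta)

    rows = []

    def add(name, variables, res):
        rows.append(
            {
                "test": res.name, "variables": variables,
                "estimate": res.estimate, "p": res.p, "n": res.n,
                "covariates": "+".join(res.covariates) if res.covariates else "none",
                "label": name,
            }
        )

    if is_mdd.any() and (~is_mdd).any():
        add(
            "symptom_group_difference", "symptom ~ group",
            ranksum_test(symptom[is_mdd], symptom[~is_mdd]),
        )
    for col in ("w0", "w_rpe", "w_cr", "w_ev", "gamma", "r2"):
        vals = full[col].to_numpy(float)
        add(f"{col}_vs_symptom", f"{col} ~ symptom", spearman(vals, symptom))
        add(
            f"{col}_vs_symptom_residualized", f"{col} ~ symptom | sex+degree+age",
            residualized_spearman(vals, symptom, cov),
        )
        if is_mdd.any() and (~is_mdd).any():
            add(
                f"{col}_group_difference", f"{col} ~ group",
                ranksum_test(vals[is_mdd], vals[~is_mdd]),
            )
    return pd.DataFrame(rows)


def replicate(config: CohortConfig | dict, out_dir) -> Path:
    """Run the full pipeline into ``out_dir`` and write a run manifest.

    Stages: cohort simulation (sessions + metadata), per-participant fits
    under all three model specs, fixed-effects model comparison, and the
    group statistics table.  For the scanner variant, the >30-missed-trial
    exclusion is applied and reported instead of mood-model fitting.
    """
    cfg = config_from_dict(config) if isinstance(config, dict) else config
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions_dir = out / "sessions"
    sessions_dir.mkdir(exist_ok=True)

    log.info("stage 1/4: simulating cohort (seed=%d)", cfg.seed)
    cohort = generate_cohort(cfg)
    files = []
    for p in cohort.participants:
        f = sessions_dir / f"{p.id}.tsv"
        write_session(p.session, f)
        files.append(f)
    meta = cohort.metadata_frame()
    meta_path = out / "participants.tsv"
    meta.to_csv(meta_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(meta_path)
    log.info("cohort: %d participants in", len(cohort))

    if cfg.variant == "probabilistic":
        counts = [p.missed_observation_count for p in cohort.participants]
        kept = apply_exclusion(cohort.participants, counts)
        log.info("exclusion filter: %d in, %d retained", len(cohort), len(kept))
        kept_ids = {p.id for p in kept}
        summary = pd.DataFrame(
            [
                {
                    "n_in": len(cohort),
                    "n_retained": len(kept),
                    "n_excluded": len(cohort) - len(kept),
                    "threshold": 30,
                }
            ]
        )
        spath = out / "exclusion_summary.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        files.append(spath)
        meta_kept = meta[meta["id"].isin(kept_ids)]
        acc = 1.0 - meta_kept["missed_observation_count"].to_numpy(float) / 164.0
        grp = (meta_kept["group"] == "MDD").to_numpy()
        srows = []
        if grp.any() and (~grp).any():
            res = ranksum_test(acc[grp], acc[~grp])
            srows.append(
                {
                    "test": res.name, "variables": "accuracy ~ group",
                    "estimate": res.estimate, "p": res.p, "n": res.n,
                    "covariates": "none", "label": "accuracy_group_difference",
                }
            )
        stats_df = pd.DataFrame(srows)
    else:
        log.info("stage 2/4: fitting mood models")
        fits = fit_cohort(cohort)
        fit_df = fits_frame(fits)
        fit_path = out / "fits.tsv"
        fit_df.to_csv(fit_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        files.append(fit_path)

        log.info("stage 3/4: model comparison (BIC approximation, fixed effects)")
        cmp = compare_models(fits)
        cmp_df = pd.DataFrame(
            [
                {
                    "spec": sid,
                    "total_ic": cmp.total_ic[sid],
                    "best_for_n_participants": cmp.best_counts[sid],
                    "winner": int(sid in cmp.winners),
                }
                for sid in sorted(cmp.total_ic)
            ]
        )
        cmp_path = out / "model_comparison.tsv"
        cmp_df.to_csv(cmp_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        files.append(cmp_path)

        log.info("stage 4/4: group statistics")
        stats_df = stats_table(meta, fit_df)

    stats_path = out / "stats.tsv"
    stats_df.to_csv(stats_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(stats_path)

    cfg_dict = config_to_dict(cfg)
    cfg_path = out / "config.yaml"
    write_config(cfg_dict, cfg_path)
    files.append(cfg_path)
    write_manifest(out, cfg_dict, {"cohort": cfg.seed}, files)
    log.info("pipeline complete: %s", out)
    return out
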