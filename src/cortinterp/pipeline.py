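"""End-to-end study replica: simulate -> downsample -> validate ->
interpolate -> estimate -> test.

For every subject x condition x specimen the pipeline fits the ground-truth
profile at all degrees, downsamples onto each alternative scheme, runs the
polynomial validation, scores every alternative fit against the ground-truth
data, runs the 100-iteration stochastic-interpolation ensemble per
scheme x degree, regenerates each optimal iteration for its 24 h output,
and finally produces the output table, the paired TOST equivalence table
and the two-way ANOVA.  Everything is deterministic given the run config
and master seed.

:func:`select_optimal_degree` codifies the qualitative "plateau" judgement
as an explicit two-threshold rule: pick the smallest degree whose mean
alternative-model R2 gain to the next degree falls below a plateau
threshold while its mean ensemble RMSE stays within a tolerance of the
best across degrees (RMSE curves are normalised per scheme by their own
minimum before averaging, so schemes with different degree caps compare
fairly).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equivalence import (
    EquivalenceResult,
    OutputEstimate,
    TOSTConfig,
    anova_outputs,
    build_output_table,
    total_output,
    tost_paired,
)
from .fitting import PolyFit, metrics_against, polynomial_validation
from .interpolation import IterationEnsemble, ensemble, regenerate_optimal
from .profiles import Profile, SPECIMENS, write_cohort_csv
from .schemes import GROUND_TRUTH, alternative_schemes_for, build_scheme, downsample
from .synthetic import CohortConfig, generate_cohort

ProfileKey = tuple[str, str, str]  # (subject_id, condition, specimen)
EnsembleKey = tuple[str, str, str, str, int]  # + (scheme, degree)


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_iter: int = 100
    master_seed: int = 0
    tost: TOSTConfig = field(default_factory=TOSTConfig)
    table_degrees: tuple[int, ...] = (2, 3)
    error_model: str = "truncnorm"
    residual_scale: str = "rse"
    plateau_threshold: float = 0.02
    rmse_tolerance: float = 0.10

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "n_iter": self.n_iter,
            "master_seed": self.master_seed,
            "tost": {
                "epsilon": self.tost.epsilon,
                "alpha": self.tost.alpha,
                "log_transform": self.tost.log_transform,
            },
            "table_degrees": list(self.table_degrees),
            "error_model": self.error_model,
            "residual_scale": self.residual_scale,
            "plateau_threshold": self.plateau_threshold,
            "rmse_tolerance": self.rmse_tolerance,
        }


@dataclass
class RunResult:
    """All artifacts of one pipeline run."""

    config: RunConfig
    cohort: list[Profile]
    ground_truth_fits: dict[ProfileKey, list[PolyFit]]
    alternative_fits: dict[tuple[ProfileKey, str], list[PolyFit]]
    ensembles: dict[EnsembleKey, IterationEnsemble]
    metrics: pd.DataFrame
    outputs: list[OutputEstimate]
    output_table: pd.DataFrame
    tost_table: pd.DataFrame
    anova: pd.DataFrame
    optimal_degrees: dict[str, int]
    manifest: dict


def _ensemble_seed(master_seed: int, key: EnsembleKey) -> int:
    """Stable per-ensemble seed derived from the master seed and the key."""
    digest = hashlib.sha256(("|".join(map(str, key))).encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return int(np.random.SeedSequence((int(master_seed), tag)).generate_state(1)[0])


def run_pipeline(config: RunConfig, cohort: list[Profile] | None = None) -> RunResult:
    """Execute the full analysis; see the module docstring for the stages."""
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    by_key = {p.key: p for p in cohort}

    gt_fits: dict[ProfileKey, list[PolyFit]] = {}
    alt_fits: dict[tuple[ProfileKey, str], list[PolyFit]] = {}
    ensembles: dict[EnsembleKey, IterationEnsemble] = {}
    metric_rows = []
    outputs: list[OutputEstimate] = []

    specimens = sorted({p.specimen for p in cohort}, reverse=True)  # serum first
    for key in sorted(by_key):
        profile = by_key[key]
        subject_id, condition, specimen = key
        gt_scheme = build_scheme(GROUND_TRUTH[specimen])
        if not np.array_equal(profile.times, gt_scheme.grid_minutes):
            raise ValueError(
                f"profile {key} does not lie on its ground-truth grid "
                f"({gt_scheme.name})"
            )
        gt_fits[key] = polynomial_validation(profile, gt_scheme)
        outputs.append(
            OutputEstimate(
                subject_id, condition, specimen, gt_scheme.name,
                total_output(profile), source="observed",
            )
        )
        for scheme in alternative_schemes_for(specimen):
            observed = downsample(profile, scheme)
            fits = polynomial_validation(observed, scheme)
            alt_fits[(key, scheme.name)] = fits
            outputs.append(
                OutputEstimate(
                    subject_id, condition, specimen, scheme.name,
                    total_output(observed), source="observed",
                )
            )
            for fit in fits:
                degree = fit.degree
                vs_truth = metrics_against(fit, profile)
                ekey: EnsembleKey = (subject_id, condition, specimen, scheme.name, degree)
                ens = ensemble(
                    fit,
                    observed,
                    gt_fits[key][degree - 1],
                    gt_scheme.grid_minutes,
                    n_iter=config.n_iter,
                    master_seed=_ensemble_seed(config.master_seed, ekey),
                    error_model=config.error_model,
                    residual_scale=config.residual_scale,
                )
                ensembles[ekey] = ens
                optimal = regenerate_optimal(fit, observed, gt_scheme.grid_minutes, ens)
                outputs.append(
                    OutputEstimate(
                        subject_id, condition, specimen, scheme.name,
                        total_output(optimal), source="interpolated", degree=degree,
                    )
                )
                metric_rows.append(
                    {
                        "subject_id": subject_id,
                        "condition": condition,
                        "specimen": specimen,
                        "scheme": scheme.name,
                        "degree": degree,
                        "r2_self": fit.r2_self,
                        "rmse_self": fit.rmse_self,
                        "r2_vs_truth": vs_truth.r2,
                        "rmse_vs_truth": vs_truth.rmse,
                        "ens_r2_peak": ens.r2_peak,
                        "ens_rmse_peak": ens.rmse_peak,
                        "ens_rmse_mean": float(ens.rmse_values.mean()),
                        "optimal_seed": ens.optimal_seed,
                    }
                )

    metrics = pd.DataFrame(metric_rows)
    output_table = build_output_table(outputs, degrees=config.table_degrees)
    tost_table = _tost_table(outputs, config)
    gt_outputs = [
        o for o in outputs
        if o.source == "observed" and o.scheme == GROUND_TRUTH[o.specimen]
    ]
    anova = (
        anova_outputs(gt_outputs)
        if {o.specimen for o in gt_outputs} == set(SPECIMENS)
        else pd.DataFrame()
    )

    result = RunResult(
        config=config,
        cohort=cohort,
        ground_truth_fits=gt_fits,
        alternative_fits=alt_fits,
        ensembles=ensembles,
        metrics=metrics,
        outputs=outputs,
        output_table=output_table,
        tost_table=tost_table,
        anova=anova,
        optimal_degrees={},
        manifest={},
    )
    for specimen in specimens:
        result.optimal_degrees[specimen] = select_optimal_degree(result, specimen)
    result.manifest = _build_manifest(result)
    return result


def _tost_table(outputs: list[OutputEstimate], config: RunConfig) -> pd.DataFrame:
    """Paired TOST of interpolated vs ground-truth observed outputs,
    one row per specimen x condition x scheme x degree."""
    frame = pd.DataFrame([o.__dict__ for o in outputs])
    rows = []
    for specimen in frame["specimen"].unique():
        gt_name = GROUND_TRUTH[specimen]
        for condition in frame["condition"].unique():
            base = frame[
                (frame["specimen"] == specimen)
                & (frame["condition"] == condition)
                & (frame["scheme"] == gt_name)
                & (frame["source"] == "observed")
            ].set_index("subject_id")["auc"]
            if len(base) < 3:
                continue
            interp = frame[
                (frame["specimen"] == specimen)
                & (frame["condition"] == condition)
                & (frame["source"] == "interpolated")
            ]
            for (scheme, degree), grp in interp.groupby(["scheme", "degree"]):
                if degree not in config.table_degrees:
                    continue
                y = grp.set_index("subject_id")["auc"].reindex(base.index)
                res = tost_paired(base.to_numpy(), y.to_numpy(), config.tost)
                rows.append(
                    {
                        "specimen": specimen,
                        "condition": condition,
                        "scheme": scheme,
                        "degree": int(degree),
                        "estimate": res.estimate,
                        "ci_lower": res.ci_lower,
                        "ci_upper": res.ci_upper,
                        "p_lower": res.p_lower,
                        "p_upper": res.p_upper,
                        "cohens_d": res.cohens_d,
                        "equivalent": res.equivalent,
                    }
                )
    columns = [
        "specimen", "condition", "scheme", "degree", "estimate",
        "ci_lower", "ci_upper", "p_lower", "p_upper", "cohens_d", "equivalent",
    ]
    return pd.DataFrame(rows, columns=columns)


def select_optimal_degree(
    result: RunResult,
    specimen: str,
    plateau_threshold: float | None = None,
    rmse_tolerance: float | None = None,
) -> int:
    """Smallest degree at the joint R2/RMSE plateau for a specimen.

    Criterion (a): the mean R2-vs-ground-truth gain from degree d to d+1
    (averaged over schemes supporting both) is below ``plateau_threshold``.
    Criterion (b): the mean ensemble RMSE at d, normalised per scheme by
    that scheme's own minimum across degrees, is within ``rmse_tolerance``
    of 1.  If no degree satisfies both, the degree with the lowest mean
    normalised RMSE is returned with a warning.
    """
    thr = plateau_threshold if plateau_threshold is not None else result.config.plateau_threshold
    tol = rmse_tolerance if rmse_tolerance is not None else result.config.rmse_tolerance
    sub = result.metrics[result.metrics["specimen"] == specimen]
    if sub.empty:
        raise ValueError(f"no metrics for specimen {specimen!r}")

    r2 = sub.groupby(["scheme", "degree"])["r2_vs_truth"].mean()
    rmse_m = sub.groupby(["scheme", "degree"])["ens_rmse_mean"].mean()
    schemes = sorted(sub["scheme"].unique())
    degrees = sorted(sub["degree"].unique())

    candidates = []
    for d in degrees:
        pair = [s for s in schemes if (s, d) in r2.index and (s, d + 1) in r2.index]
        gain = float(np.mean([r2[(s, d + 1)] - r2[(s, d)] for s in pair])) if pair else 0.0
        ratios = []
        for s in schemes:
            if (s, d) not in rmse_m.index:
                continue
            best_rmse = min(rmse_m[s])
            value = rmse_m[(s, d)]
            if best_rmse == 0.0:
                ratios.append(1.0 if value == 0.0 else float("inf"))
            else:
                ratios.append(value / best_rmse)
        mean_ratio = float(np.mean(ratios))
        candidates.append((int(d), gain, mean_ratio))
        if gain < thr and mean_ratio <= 1.0 + tol:
            return int(d)
    best = min(candidates, key=lambda c: c[2])[0]
    warnings.warn(
        f"no degree met both plateau criteria for {specimen}; "
        f"returning degree {best} with the lowest mean normalised RMSE"
    )
    return best


def _build_manifest(result: RunResult) -> dict:
    cfg = result.config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "version": __version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "master_seed": result.config.master_seed,
        "n_profiles": len(result.cohort),
        "n_ensembles": len(result.ensembles),
        "optimal_degrees": result.optimal_degrees,
        "optimal_seeds": {
            "|".join(map(str, k)): v.optimal_seed for k, v in result.ensembles.items()
        },
    }


def write_run(result: RunResult, outdir) -> dict:
    """Write all run artifacts under ``outdir``; returns the manifest
    (extended with the artifact paths)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": "cohort.csv",
        "metrics": "metrics.csv",
        "output_table": "output_table.csv",
        "tost": "tost.csv",
        "anova": "anova.csv",
        "ensembles": "ensembles.json",
        "manifest": "manifest.json",
    }
    write_cohort_csv(result.cohort, outdir / paths["cohort"])
    result.metrics.to_csv(outdir / paths["metrics"], index=False)
    result.output_table.to_csv(outdir / paths["output_table"], index=False)
    result.tost_table.to_csv(outdir / paths["tost"], index=False)
    result.anova.to_csv(outdir / paths["anova"], index=False)
    with open(outdir / paths["ensembles"], "w") as fh:
        json.dump(
            {"|".join(map(str, k)): v.to_dict() for k, v in result.ensembles.items()},
            fh,
            sort_keys=True,
        )
    manifest = dict(result.manifest, artifacts=paths)
    with open(outdir / paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
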