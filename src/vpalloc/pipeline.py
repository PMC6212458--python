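"""End-to-end orchestration: simulate -> fit -> compare -> behavior -> report.

A :class:`RunConfig` (constructible from YAML) fixes the experiment, the
candidate strategies, the generating model and parameters, the design, the
fitting options and every seed; :func:`run_pipeline` then produces a run
directory of CSV/JSON outputs and vector figures, with a manifest recording
the config hash and package version.  Per-participant fit failures are
logged and do not abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vpalloc import behavior
from vpalloc.fitting import FitResult, ModelSpec, compare_models, fit_model
from vpalloc.simulate import DesignConfig, generate_experiment, write_trials

logger = logging.getLogger("vpalloc.pipeline")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (all randomness via explicit seeds)."""

    experiment: int = 2
    models: tuple[str, ...] = ("proportional", "flexible")
    generating_model: str = "flexible"
    generating_theta: dict = field(
        default_factory=lambda: {
            "Jbar_total": 3.0,
            "tau": 0.5,
            "p_high": 0.44,
            "p_med": 0.31,
            "lam": 5.0,
        }
    )
    n_participants: int = 4
    n_trials: int = 300
    n_starts: int = 5
    n_perm: int = 500
    n_boot: int = 10_000
    seed: int = 0
    outdir: str = "vpalloc_run"
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {"proportional", "flexible", "minimizing_error", "maximizing_points"}
        for m in tuple(self.models) + (self.generating_model,):
            if m not in valid:
                raise ValueError(f"unknown model {m!r}")
            if m == "maximizing_points" and self.experiment != 2:
                raise ValueError("maximizing_points requires experiment 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def design(self) -> DesignConfig:
        return DesignConfig(n_trials=self.n_trials, **self.design_overrides)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    trials: pd.DataFrame
    fits: dict
    comparisons: list
    failures: list

    @property
    def ok(self) -> bool:
        return not self.failures


def _spec(config: RunConfig, strategy: str) -> ModelSpec:
    return ModelSpec(experiment=config.experiment, strategy=strategy)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline; returns outputs and a list of per-fit failures."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    design = config.design()
    gen_spec = _spec(config, config.generating_model)

    # --- simulate ---
    frames = []
    sim_seeds = ss.spawn(config.n_participants)
    for pid, child in enumerate(sim_seeds):
        frames.append(
            generate_experiment(
                gen_spec,
                config.generating_theta,
                design,
                rng_seed=child.generate_state(1)[0] % 2**31,
                participant=pid,
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    write_trials(
        trials,
        out / "trials.csv",
        meta={
            "design": design,
            "generating_model": config.generating_model,
            "generating_theta": config.generating_theta,
            "seed": config.seed,
        },
    )

    # --- fit each model per participant ---
    fits: dict[str, dict[int, FitResult]] = {m: {} for m in config.models}
    failures = []
    fit_ss = ss.spawn(1)[0]
    for strategy in config.models:
        spec = _spec(config, strategy)
        for pid, sub in trials.groupby("participant"):
            try:
                res = fit_model(
                    spec,
                    sub,
                    n_starts=config.n_starts,
                    rng_seed=np.random.default_rng(fit_ss.spawn(1)[0]),
                )
                fits[strategy][pid] = res
                logger.debug(
                    "fit %s participant %s: LL=%.2f starts=%s",
                    strategy,
                    pid,
                    res.loglik,
                    np.round(res.start_logliks, 2).tolist(),
                )
            except Exception as exc:
                failures.append({"model": strategy, "participant": pid, "error": repr(exc)})
                logger.warning("fit failed: %s participant %s: %r", strategy, pid, exc)
    fit_rows = []
    for strategy, per in fits.items():
        for pid, res in per.items():
            fit_rows.append(
                {
                    "model": strategy,
                    "participant": pid,
                    **{f"theta_{k}": v for k, v in res.theta_hat.items()},
                    "p_high": res.allocation[0],
                    "p_med": res.allocation[1],
                    "p_low": res.allocation[2],
                    "loglik": res.loglik,
                    "aicc": res.aicc,
                    "bic": res.bic,
                }
            )
    fit_table = pd.DataFrame(fit_rows)
    fit_table.to_csv(out / "fits.csv", index=False)

    # --- model comparison (each competitor against the first listed model) ---
    comparisons = []
    boot_rng = np.random.default_rng(ss.spawn(1)[0])
    ref = config.models[0]
    for strategy in config.models[1:]:
        common = set(fits[ref]) & set(fits[strategy])
        if len(common) < 2:
            continue
        comp = compare_models(
            {p: fits[ref][p] for p in common},
            {p: fits[strategy][p] for p in common},
            n_boot=config.n_boot,
            rng_seed=int(boot_rng.integers(2**31)),
        )
        comparisons.append(comp)
    if comparisons:
        pd.concat([c.to_frame() for c in comparisons], ignore_index=True).to_csv(
            out / "model_comparison.csv", index=False
        )

    # --- behavioral statistics ---
    summary = behavior.priority_summary(trials)
    summary.to_csv(out / "priority_summary.csv", index=False)
    behavior.participant_priority_table(trials).to_csv(
        out / "participant_priority_table.csv", index=False
    )
    stats_json = {"monotone_error": summary.attrs.get("monotone_error")}
    if config.experiment == 2:
        pooled, per = behavior.within_priority_correlation(trials)
        pooled.to_csv(out / "correlation_pooled.csv", index=False)
        per.to_csv(out / "correlation_per_participant.csv", index=False)
        perm_rng = np.random.default_rng(ss.spawn(1)[0])
        perm_rows = []
        for cov in ("location", "delay"):
            nulls = behavior.permutation_null(
                trials, cov, n_perm=config.n_perm, rng_seed=int(perm_rng.integers(2**31))
            )
            for nd in nulls:
                perm_rows.append(
                    {
                        "covariate": cov,
                        "participant": nd.participant,
                        "priority": nd.priority,
                        "observed_rho": nd.observed_rho,
                        "null_median": nd.null_median,
                        "observed_percentile": nd.percentile_of_observed(),
                    }
                )
        perm_table = pd.DataFrame(perm_rows)
        perm_table.to_csv(out / "permutation_tests.csv", index=False)
        for cov in ("location", "delay"):
            sub = perm_table[perm_table["covariate"] == cov]
            if len(sub) >= 5:
                sr = behavior.signed_rank_vs_null(
                    sub["observed_rho"].to_numpy(), sub["null_median"].to_numpy()
                )
                stats_json[f"signed_rank_{cov}"] = {
                    "statistic": sr.statistic,
                    "p": sr.pvalue,
                    "degenerate": sr.degenerate,
                }
        stats_json["monotone_radius"] = summary.attrs.get("monotone_radius")
    with open(out / "behavior_stats.json", "w") as fh:
        json.dump(stats_json, fh, indent=2)

    _figures(out, trials, summary, fit_table, comparisons, config)

    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "package_version": __import__("vpalloc").__version__,
        "n_failures": len(failures),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(
        outdir=out, trials=trials, fits=fits, comparisons=comparisons, failures=failures
    )


def _figures(out, trials, summary, fit_table, comparisons, config) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {0.6: "tab:red", 0.3: "tab:blue", 0.1: "black"}
    # priority effects (error, and radius when present)
    measures = [c[:-5] for c in summary.columns if c.endswith("_mean")]
    fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 3.2))
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, measures):
        ax.errorbar(
            summary["priority"],
            summary[f"{m}_mean"],
            yerr=summary[f"{m}_sem"],
            marker="o",
            color="k",
        )
        ax.set_xlabel("probe probability")
        ax.set_ylabel(f"{m} (dva)")
        ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(out / "priority_effects.pdf")
    plt.close(fig)

    # allocation estimates per model
    if len(fit_table):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for i, (model, sub) in enumerate(fit_table.groupby("model")):
            for j, col in enumerate(["p_high", "p_med", "p_low"]):
                ax.scatter(
                    np.full(len(sub), j + i * 0.15 - 0.07),
                    sub[col],
                    s=14,
                    label=model if j == 0 else None,
                )
        for j, pr in enumerate([0.6, 0.3, 0.1]):
            ax.hlines(pr, j - 0.25, j + 0.25, color=colors[pr], lw=2)
        ax.set_xticks([0, 1, 2], ["high", "medium", "low"])
        ax.set_ylabel("proportion allocated")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "allocation_estimates.pdf")
        plt.close(fig)

    # model comparison
    if comparisons:
        fig, ax = plt.subplots(figsize=(4, 3.2))
        for i, comp in enumerate(comparisons):
            d = comp.per_participant["delta_aicc"]
            ax.scatter(np.full(len(d), i), d, s=12, color="0.5")
            ax.hlines(comp.median_delta_aicc, i - 0.2, i + 0.2, color="k", lw=2)
            ax.fill_between(
                [i - 0.2, i + 0.2], *[[v, v] for v in comp.ci_delta_aicc], alpha=0.2, color="0.6"
            )
        ax.set_xticks(
            range(len(comparisons)), [f"{c.first}\n- {c.second}" for c in comparisons], fontsize=7
        )
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("delta AICc")
        fig.tight_layout()
        fig.savefig(out / "model_comparison.pdf")
        plt.close(fig)
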