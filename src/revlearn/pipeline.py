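"""End-to-end analysis pipeline and bundled-fixture generator.

Sequences the full analysis on one cohort: simulate (or ingest) an event
log -> fit the candidate models per group -> LOOIC comparison -> hypermean
group differences -> model-free behavioral metrics -> posterior-predictive
simulation.  Every run writes a manifest listing each produced file with
the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inference import McmcSettings, fit_hierarchical, group_difference
from .metrics import p_correct_by_session, wsls_table
from .models import Model
from .ppc import ppc_wsls, simulate_from_fit
from .selection import compare_models, loo_from_fit
from .task import (
    CohortData,
    GroupSpec,
    TaskConfig,
    default_group_specs,
    generate_cohort,
    write_event_log,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]

log = logging.getLogger("revlearn")


@dataclass
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    groups: list[GroupSpec] = field(default_factory=list)
    models: list[Model] = field(default_factory=lambda: [Model.RP, Model.FICT, Model.FICT_RP])
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0
    outdir: Path = Path("revlearn_out")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        task = TaskConfig(**d.get("task", {}))
        groups = []
        for g in d.get("groups", []):
            model = Model(int(g.get("model", 3)))
            if "constrained_means" in g:
                spec = GroupSpec.from_constrained(
                    g["name"],
                    int(g["n_subjects"]),
                    g["constrained_means"],
                    g.get("sd", 0.2),
                    model,
                )
            else:
                spec = GroupSpec(
                    g["name"], int(g["n_subjects"]), g["hyper_mean"], g["hyper_sd"], model
                )
            groups.append(spec)
        if not groups:
            raise ValueError("config must define at least one group")
        models = [Model(int(m)) for m in d.get("models", [1, 2, 3])]
        mcmc = McmcSettings(**d.get("mcmc", {}))
        return cls(
            task=task,
            groups=groups,
            models=models,
            mcmc=mcmc,
            seed=int(d.get("seed", 0)),
            outdir=Path(d.get("outdir", "revlearn_out")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = {
            "task": asdict(self.task),
            "groups": [
                {
                    "name": g.name,
                    "n_subjects": g.n_subjects,
                    "hyper_mean": dict(g.hyper_mean),
                    "hyper_sd": dict(g.hyper_sd),
                    "model": int(g.model),
                }
                for g in self.groups
            ],
            "models": [int(m) for m in self.models],
            "mcmc": asdict(self.mcmc),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage(manifest: dict, name: str, t0: float, outputs: list[Path]) -> None:
    dt = time.perf_counter() - t0
    manifest["stages"].append(
        {"stage": name, "seconds": round(dt, 2), "outputs": [str(p) for p in outputs]}
    )
    log.info("stage=%s seconds=%.2f outputs=%s", name, dt, [str(p) for p in outputs])


def run_pipeline(config: RunConfig, cohort: CohortData | None = None) -> dict:
    """Run the full analysis; returns (and writes) the manifest.

    If ``cohort`` is None a synthetic cohort is generated from
    ``config.groups``; otherwise the supplied event log is analyzed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
    }
    try:
        t0 = time.perf_counter()
        if cohort is None:
            cohort = generate_cohort(config.groups, config.task, master_seed=config.seed)
        cohort_csv = out / "cohort.csv"
        write_event_log(cohort, cohort_csv)
        outputs = [cohort_csv]
        if cohort.params is not None:
            p = out / "params_true.csv"
            cohort.params.to_csv(p, index=False)
            outputs.append(p)
        _stage(manifest, "simulate", t0, outputs)

        # fit every candidate model per group, collect LOO per group
        all_fits: dict[Model, dict] = {}
        loo_rows = []
        for model in config.models:
            t0 = time.perf_counter()
            fits = fit_hierarchical(model, cohort, config.mcmc, seed=config.seed + 10 * int(model))
            all_fits[model] = fits
            outputs = []
            for gname, fit in fits.items():
                p = out / f"fit_summary_model{int(model)}_{gname}.csv"
                fit.summary().to_csv(p, index=False)
                outputs.append(p)
            _stage(manifest, f"fit_model{int(model)}", t0, outputs)

        t0 = time.perf_counter()
        outputs = []
        for gname in sorted(cohort.groups):
            results = [(m, loo_from_fit(all_fits[m][gname])) for m in config.models]
            comp = compare_models(results)
            p = out / f"model_comparison_{gname}.csv"
            comp.to_csv(p, index=False)
            outputs.append(p)
            loo_rows.append(comp.assign(group=gname))
        _stage(manifest, "compare", t0, outputs)

        # hyperposterior group differences for the most general fitted model
        t0 = time.perf_counter()
        best_model = config.models[-1]
        fits = all_fits[best_model]
        outputs = []
        if len(fits) == 2:
            gs = sorted(fits)
            rows = []
            for param in best_model.param_names:
                d = group_difference(fits[gs[1]], fits[gs[0]], param)
                rows.append(
                    {
                        "param": param,
                        "comparison": f"{gs[1]} - {gs[0]}",
                        "mean_diff": float(d.draws.mean()),
                        "hdi_low": d.interval.lower,
                        "hdi_high": d.interval.upper,
                        "excludes_zero": d.excludes_zero,
                    }
                )
            p = out / "group_differences.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            outputs.append(p)
        _stage(manifest, "group_differences", t0, outputs)

        t0 = time.perf_counter()
        wsls_csv = out / "wsls.csv"
        wsls_table(cohort.trials).to_csv(wsls_csv, index=False)
        psess_csv = out / "p_correct_by_session.csv"
        p_correct_by_session(cohort.trials).to_csv(psess_csv, index=False)
        _stage(manifest, "metrics", t0, [wsls_csv, psess_csv])

        t0 = time.perf_counter()
        simulated = simulate_from_fit(fits, config.task, seed=config.seed + 99)
        ppc = ppc_wsls(cohort, simulated)
        ppc_subj = out / "ppc_per_subject.csv"
        ppc.per_subject.to_csv(ppc_subj, index=False)
        ppc_tests = out / "ppc_group_tests.csv"
        ppc.group_tests.to_csv(ppc_tests, index=False)
        _stage(manifest, "posterior_simulation", t0, [ppc_subj, ppc_tests])
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# bundled fixtures

#: The 3-trial hand-checkable sequence: choices A, A, B with outcomes
#: reward, omission, omission; high side A throughout.
HAND_FIXTURE_ROWS = [
    ("hand_01", "demo", 1, 1, "A", "A", 1),
    ("hand_01", "demo", 1, 2, "A", "A", 0),
    ("hand_01", "demo", 1, 3, "A", "B", 0),
]


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the two bundled datasets: (a) the 3-trial hand-replay log and
    (b) a small 2-group x 4-subject x 2-session cohort for fast checks."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hand = out / "hand_three_trials.csv"
    df = pd.DataFrame(
        HAND_FIXTURE_ROWS,
        columns=["subject_id", "group", "session", "trial", "high_side", "choice", "rewarded"],
    )
    df.to_csv(hand, index=False)

    config = TaskConfig(n_sessions=2)
    cohort = generate_cohort(
        default_group_specs(n_control=4, n_mutant=4), config, master_seed=seed
    )
    small = out / "cohort_small.csv"
    write_event_log(cohort, small)
    return {"hand": hand, "cohort_small": small}


def load_hand_fixture() -> pd.DataFrame:
    """The 3-trial fixture as an in-memory trial table."""
    return pd.DataFrame(
        HAND_FIXTURE_ROWS,
        columns=["subject_id", "group", "session", "trial", "high_side", "choice", "rewarded"],
    ).assign(rewarded=lambda d: d["rewarded"].astype(bool))
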