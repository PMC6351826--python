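"""End-to-end orchestration: betas + clocks -> eAge + broken-stick reports;
expression + panels -> cluster assignments and composite trajectories.

A run is described by a declarative config (YAML on disk, a dict in
memory); every output carries the seed and a hash of the resolved config so
reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import breakpoint as bstick
from . import clocks as ck
from . import simulate as sim
from .trajectories import GenePanel, cluster_trajectories, normalize_panel, read_panel

log = logging.getLogger("rejuvotrack")

__all__ = ["RunConfig", "run_eage", "run_expression", "run_all", "make_fixtures"]


@dataclass
class RunConfig:
    clocks: list[str] = field(default_factory=list)
    betas: str | None = None
    expression: str | None = None
    sample_sheet: str | None = None
    panels: list[str] = field(default_factory=list)
    window: tuple[float, float] = (3.0, 49.0)
    grid: list[float] | None = None           # None = default candidate policy
    missing_policy: str = "error"
    k_range: list[int] = field(default_factory=lambda: list(range(1, 7)))
    n_restarts: int = 10
    seed: int = 0
    out: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.k_range is not None and len(cfg.k_range) == 0:
            raise ValueError("k_range must not be empty")
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        d["window"] = list(d["window"])
        d.pop("out")  # the output path is not a scientific parameter
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.digest()}


def run_eage(cfg: RunConfig) -> dict[str, bstick.BrokenStickFit]:
    """Per clock: predict ages, aggregate the time course, fit the broken
    stick; write one eAge CSV and one fit JSON per clock.

    Clocks failing probe coverage are logged and skipped; the run fails only
    if no clock succeeds.
    """
    if not cfg.clocks:
        raise ValueError("config lists no clock files")
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    betas = ck.BetaMatrix.read_csv(cfg.betas)
    sheet = ck.read_sample_sheet(cfg.sample_sheet)

    fits: dict[str, bstick.BrokenStickFit] = {}
    failures: dict[str, str] = {}
    for clock_path in cfg.clocks:
        clock = ck.load_clock(clock_path)
        n_covered = sum(p in betas.values.index for p in clock.probes)
        log.info(
            "clock %s: %d/%d probes covered", clock.name, n_covered, len(clock.probes)
        )
        try:
            eages = ck.predict_age(clock, betas, missing_policy=cfg.missing_policy)
        except (ck.MissingProbeError, ValueError) as exc:
            log.warning("clock %s failed: %s", clock.name, exc)
            failures[clock.name] = str(exc)
            continue
        merged = eages.merge(sheet, on="sample")
        merged[["sample", "day", "replicate", "clock", "eage", "n_missing_probes"]].to_csv(
            outdir / f"eage_{clock.name}.csv", index=False
        )
        tc = bstick.aggregate_timecourse(eages, sheet)
        fit = bstick.fit_broken_stick(tc, window=tuple(cfg.window), grid=cfg.grid)
        fit.to_json(outdir / f"fit_{clock.name}.json", clock=clock.name, **_provenance(cfg))
        fits[clock.name] = fit
    if not fits:
        raise RuntimeError(f"no clock succeeded: {failures}")
    return fits


def run_expression(cfg: RunConfig):
    """Per panel: normalize trajectories, cluster, write assignment CSV,
    composite CSV, and a selection report JSON."""
    if not cfg.panels:
        raise ValueError("config lists no panel files")
    if not cfg.k_range:
        raise ValueError("k_range must not be empty")
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = pd.read_csv(cfg.expression, sep=None, engine="python", index_col=0)
    sheet = ck.read_sample_sheet(cfg.sample_sheet)

    results = {}
    for panel_path in cfg.panels:
        panel = read_panel(panel_path)
        stem = Path(panel_path).stem
        ts = normalize_panel(expr, panel, sheet)
        cr = cluster_trajectories(
            ts, k_range=cfg.k_range, n_restarts=cfg.n_restarts, seed=cfg.seed
        )
        if panel.unhinted:
            log.info("panel %s: unhinted markers clustered anyway: %s", stem, panel.unhinted)
        assignment = panel.table[["probe", "marker"]].copy()
        assignment["cluster"] = cr.assignment.reindex(panel.probes).to_numpy()
        assignment.to_csv(outdir / f"assignment_{stem}.csv", index=False)
        cr.composite.to_csv(outdir / f"composite_{stem}.csv", index=False)
        (outdir / f"selection_{stem}.json").write_text(
            json.dumps(
                {
                    "k": cr.k,
                    "criterion": {str(k): v for k, v in cr.criterion.items()},
                    "unhinted_markers": panel.unhinted,
                    **_provenance(cfg),
                },
                indent=2,
            )
            + "\n"
        )
        results[stem] = cr
    return results


def run_all(cfg: RunConfig):
    out = {}
    if cfg.clocks:
        out["fits"] = run_eage(cfg)
    if cfg.panels:
        out["clusters"] = run_expression(cfg)
    if not out:
        raise ValueError("config lists neither clocks nor panels")
    return out


def make_fixtures(outdir, seed: int = 0) -> RunConfig:
    """Materialize the default synthetic scenario plus a ready-to-run config.

    Writes a toy clock, a beta matrix + sample sheet realizing the default
    eAge trajectory, a planted two-template expression matrix with its
    panel, and ``run.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clock = sim.make_toy_clock()
    ck.write_clock(clock, outdir / "toy_clock.txt")
    spec = sim.TrajectorySpec(seed=seed)
    betas, sheet, info = sim.synth_beta_course(clock, spec)
    betas.to_csv(outdir / "betas.csv")
    sheet.to_csv(outdir / "samples.csv", index=False)
    log.info("fixtures: %d beta entries clipped", info["n_clipped"])

    expr, esheet, panel, _truth = sim.synth_expression_course(
        sim.pluripotency_like_templates(), seed=seed + 1
    )
    expr.to_csv(outdir / "expression.csv", index_label="probe")
    panel.to_csv(outdir / "panel_synthetic_pluripotency.csv", index=False)

    cfg = RunConfig(
        clocks=[str(outdir / "toy_clock.txt")],
        betas=str(outdir / "betas.csv"),
        expression=str(outdir / "expression.csv"),
        sample_sheet=str(outdir / "samples.csv"),
        panels=[str(outdir / "panel_synthetic_pluripotency.csv")],
        seed=seed,
        out=str(outdir / "results"),
    )
    d = asdict(cfg)
    d["window"] = list(d["window"])
    (outdir / "run.yaml").write_text(yaml.safe_dump(d, sort_keys=False))
    return cfg
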