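"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators:

* :func:`synth_beta_course` builds a methylation beta matrix whose
  clock-predicted age follows a prescribed piecewise-linear reprogramming
  trajectory (decline at a constant rate from a start day to a breakpoint,
  then a plateau) with replicate-level age noise. The construction inverts
  the clock: for each sample the target age is mapped through the forward
  age transform to a required score, and the beta profile is shifted from a
  mid-range base along the clock's weight vector to hit that score exactly.
  Methylation-level noise is added *orthogonally* to the weight vector, so
  beta noise and age noise are independently controllable knobs — naive
  i.i.d. beta noise would confound the two.

* :func:`synth_expression_course` plants trajectory templates (early/late
  pluripotency activation, stepwise fibroblast decline) into a linear-scale
  expression matrix, returning ground-truth labels for clustering recovery
  scoring.

Defaults encode the reprogramming scenario the pipeline targets: the
10-point day grid {0, 3, 7, 11, 15, 20, 28, 35, 42, 49}, a decline of
-3.8 years/day from day 3 to a breakpoint at day 20, a stable plateau at
0 years afterwards, 3 replicates per day, and 2 years of replicate age
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clocks import BetaMatrix, ClockSpec, forward_transform

__all__ = [
    "TrajectorySpec",
    "TemplateSpec",
    "DEFAULT_DAYS",
    "target_age",
    "make_toy_clock",
    "synth_beta_course",
    "synth_expression_course",
    "pluripotency_like_templates",
    "fibroblast_like_templates",
    "GeneratorError",
]

DEFAULT_DAYS = (0.0, 3.0, 7.0, 11.0, 15.0, 20.0, 28.0, 35.0, 42.0, 49.0)


class GeneratorError(RuntimeError):
    """The requested trajectory is unreachable for the given clock."""


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-linear eAge scenario for the beta-matrix generator.

    The trajectory holds ``start_age`` until ``decline_start_day``, declines
    at ``rate`` (years/day, negative) until ``breakpoint``, and sits at
    ``plateau_age`` afterwards. The defaults are exactly continuous
    (64.6 = 3.8 x 17 years over days 3-20, plateau 0).
    """

    days: tuple[float, ...] = DEFAULT_DAYS
    start_age: float = 64.6
    decline_start_day: float = 3.0
    breakpoint: float = 20.0
    rate: float = -3.8
    plateau_age: float = 0.0
    n_replicates: int = 3
    noise_sd_age: float = 2.0
    noise_sd_beta: float = 0.01
    seed: int = 0

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if not (days[0] <= self.breakpoint <= days[-1]):
            raise ValueError("breakpoint must lie within the day grid's span")
        if self.plateau_age < 0:
            raise ValueError("plateau_age must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_age < 0 or self.noise_sd_beta < 0:
            raise ValueError("noise SDs must be >= 0")


def target_age(spec: TrajectorySpec, day: float) -> float:
    """Noise-free target eAge at ``day`` under ``spec``.

    Days at or before the breakpoint follow the (plateau-floored) linear
    decline; days after the breakpoint sit at ``plateau_age`` exactly.
    """
    days = np.asarray(spec.days, dtype=float)
    if not (days[0] <= day <= days[-1]):
        raise ValueError(f"day {day} outside the grid span [{days[0]}, {days[-1]}]")
    if day > spec.breakpoint:
        return float(spec.plateau_age)
    decline = spec.start_age + spec.rate * max(day - spec.decline_start_day, 0.0)
    return float(max(decline, spec.plateau_age))


def make_toy_clock(
    n_probes: int = 50,
    seed: int = 22,
    weight_sd: float = 0.5,
    adult_age: float = 20.0,
    base_age: float = 65.0,
    name: str = "toy-loglinear",
) -> ClockSpec:
    """A small log-linear clock for fixtures and oracle tests.

    Weights are drawn N(0, ``weight_sd``); the intercept is set so the
    all-0.5 base beta profile predicts ``base_age`` years. Large enough that
    the default trajectory is reachable without clipping, small enough for
    brute-force cross-checks.
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, weight_sd, size=n_probes)
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    intercept = forward_transform(base_age, adult_age) - 0.5 * weights.sum()
    return ClockSpec(
        name=name,
        intercept=float(intercept),
        coefficients=dict(zip(probes, weights.tolist())),
        transform="log-linear",
        adult_age=adult_age,
    )


def synth_beta_course(
    clock: ClockSpec,
    spec: TrajectorySpec,
    age_floor: float = 0.0,
    max_clip_fraction: float = 0.01,
):
    """Generate a beta matrix realizing ``spec``'s eAge trajectory under ``clock``.

    Per sample: target age = :func:`target_age` plus N(0, ``noise_sd_age``)
    replicate noise, floored at ``age_floor`` (log-linear clocks are
    undefined at or below -1 year; the floor also reflects that a fully
    reprogrammed epigenome does not predict meaningfully negative ages).
    The beta profile is ``b0 + (s - score(b0)) * w / ||w||^2`` with b0 = 0.5
    everywhere and ``s`` the forward-transformed target, plus beta noise
    projected orthogonal to ``w``, clipped to [0, 1].

    Returns ``(BetaMatrix, sample sheet DataFrame, info dict)``; ``info``
    holds the realized noisy targets (``targets``) and the count of clipped
    entries (``n_clipped``). With zero beta noise and zero clipping,
    ``predict_age`` on the output reproduces the targets to 1e-6 years.

    Raises :class:`GeneratorError` when more than ``max_clip_fraction`` of
    entries must be clipped (the trajectory is unreachable for this clock).
    """
    w = clock.weights
    if w.size < 2:
        raise ValueError("clock must have >= 2 probes")
    if clock.transform != "log-linear":
        raise ValueError("synth_beta_course targets log-linear clocks")
    wnorm2 = float(w @ w)
    if wnorm2 == 0:
        raise GeneratorError("clock weights are all zero")

    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    b0 = np.full(w.size, 0.5)
    score0 = clock.intercept + float(w @ b0)

    samples, sheet_rows, targets, columns = [], [], [], []
    for day in days:
        mu = target_age(spec, float(day))
        for rep in range(1, spec.n_replicates + 1):
            age = mu + (rng.normal(0.0, spec.noise_sd_age) if spec.noise_sd_age else 0.0)
            age = max(age, age_floor)
            s = forward_transform(age, clock.adult_age)
            b = b0 + (s - score0) * w / wnorm2
            if spec.noise_sd_beta:
                eps = rng.normal(0.0, spec.noise_sd_beta, size=w.size)
                eps -= (eps @ w) / wnorm2 * w  # orthogonal: leaves the score unchanged
                b = b + eps
            sample = f"d{day:g}_r{rep}"
            samples.append(sample)
            sheet_rows.append({"sample": sample, "day": float(day), "replicate": f"r{rep}"})
            targets.append(age)
            columns.append(b)

    raw = np.column_stack(columns)
    clipped = (raw < 0.0) | (raw > 1.0)
    n_clipped = int(clipped.sum())
    if n_clipped > max_clip_fraction * raw.size:
        raise GeneratorError(
            f"{n_clipped}/{raw.size} beta entries need clipping "
            f"(> {max_clip_fraction:.0%}); use a larger clock or a tamer trajectory"
        )
    betas = BetaMatrix(
        pd.DataFrame(np.clip(raw, 0.0, 1.0), index=clock.probes, columns=samples)
    )
    sheet = pd.DataFrame(sheet_rows)
    info = {
        "targets": pd.Series(targets, index=samples, name="target_age"),
        "n_clipped": n_clipped,
    }
    return betas, sheet, info


# ---------------------------------------------------------------------------
# Expression templates


@dataclass(frozen=True)
class TemplateSpec:
    """A planted trajectory template in arbitrary (0-to-1-ish) units.

    ``shape`` gives the target normalized value at each day of the shared
    grid; ``noise_sd`` is per-gene, per-day Gaussian noise on the same scale.
    """

    name: str
    shape: tuple[float, ...]
    n_genes: int
    noise_sd: float = 0.05
    direction: str = "ascending"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def pluripotency_like_templates(noise_sd: float = 0.05) -> list[TemplateSpec]:
    """Two ascending templates: early activation (steep rise, stable by day
    ~20) and late activation (slow rise, stable by day ~28), 11 + 8 genes as
    in the published pluripotency panel's cluster sizes."""
    return [
        TemplateSpec(
            "early_activation",
            shape=(0.0, 0.10, 0.50, 0.80, 0.90, 1.00, 1.00, 1.00, 1.00, 1.00),
            n_genes=11,
            noise_sd=noise_sd,
            direction="ascending",
        ),
        TemplateSpec(
            "late_activation",
            shape=(0.0, 0.02, 0.05, 0.10, 0.20, 0.35, 0.80, 0.95, 1.00, 1.00),
            n_genes=8,
            noise_sd=noise_sd,
            direction="ascending",
        ),
    ]


def fibroblast_like_templates(noise_sd: float = 0.05) -> list[TemplateSpec]:
    """Three descending templates: slow decline (stable to day 15, last to
    reach ESC levels), plateau-then-decline, and immediate decline."""
    return [
        TemplateSpec(
            "slow_decline",
            shape=(1.00, 1.00, 0.95, 0.92, 0.90, 0.75, 0.45, 0.20, 0.05, 0.00),
            n_genes=4,
            noise_sd=noise_sd,
            direction="descending",
        ),
        TemplateSpec(
            "plateau_then_decline",
            shape=(1.00, 0.80, 0.62, 0.60, 0.60, 0.40, 0.15, 0.05, 0.00, 0.00),
            n_genes=8,
            noise_sd=noise_sd,
            direction="descending",
        ),
        TemplateSpec(
            "immediate_decline",
            shape=(1.00, 0.60, 0.38, 0.30, 0.22, 0.12, 0.04, 0.00, 0.00, 0.00),
            n_genes=7,
            noise_sd=noise_sd,
            direction="descending",
        ),
    ]


def synth_expression_course(
    templates: list[TemplateSpec],
    days=DEFAULT_DAYS,
    n_replicates: int = 3,
    seed: int = 0,
    amplitude: float = 4.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
):
    """Plant templates into a linear-scale expression matrix.

    Per gene g of template T: ``log2 expr(day) = baseline_g + amplitude *
    (T.shape[day] + eps)`` with eps ~ N(0, T.noise_sd) drawn per replicate,
    then exponentiated to the linear scale. The per-gene baseline and the
    shared amplitude are absorbed by the pipeline's affine normalization, so
    recovered trajectories match the templates up to noise.

    Returns ``(expr DataFrame, sample sheet, panel DataFrame, truth Series)``
    where ``truth`` maps probe ID -> template index (1-based) for adjusted
    Rand scoring, and ``panel`` is ready for :class:`GenePanel`.
    """
    days = np.asarray(days, dtype=float)
    for t in templates:
        if len(t.shape) != days.size:
            raise ValueError(f"template {t.name!r} shape does not match the day grid")
    directions = {t.direction for t in templates}
    if len(directions) != 1:
        raise ValueError("templates in one panel must share a direction")

    rng = np.random.default_rng(seed)
    samples = [
        f"d{day:g}_r{rep}" for day in days for rep in range(1, n_replicates + 1)
    ]
    sheet = pd.DataFrame(
        [
            {"sample": f"d{day:g}_r{rep}", "day": float(day), "replicate": f"r{rep}"}
            for day in days
            for rep in range(1, n_replicates + 1)
        ]
    )

    rows, probes, markers, truth, hints = [], [], [], [], []
    gene_idx = 0
    for t_idx, t in enumerate(templates, start=1):
        shape = np.asarray(t.shape, dtype=float)
        for g in range(t.n_genes):
            baseline = rng.normal(baseline_mean, baseline_sd)
            log2_vals = []
            for j in range(days.size):
                for _ in range(n_replicates):
                    eps = rng.normal(0.0, t.noise_sd) if t.noise_sd else 0.0
                    log2_vals.append(baseline + amplitude * (shape[j] + eps))
            rows.append(np.power(2.0, log2_vals))
            probe = f"SYN_{gene_idx:03d}"
            probes.append(probe)
            markers.append(f"{t.name}_{g}")
            truth.append(t_idx)
            hints.append(str(t_idx))
            gene_idx += 1

    expr = pd.DataFrame(np.vstack(rows), index=probes, columns=samples)
    panel = pd.DataFrame(
        {
            "marker": markers,
            "probe": probes,
            "cluster_hint": hints,
            "direction": templates[0].direction,
        }
    )
    truth = pd.Series(truth, index=pd.Index(probes, name="probe"), name="template")
    return expr, sheet, panel, truth
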