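"""Linear CpG epigenetic-clock engine.

An epigenetic clock is a linear predictor over DNA-methylation beta values:
``score = intercept + sum_i w_i * beta_i`` over a fixed CpG probe set,
optionally followed by the inverse of a piecewise log-linear age transform.
The transform (used by the multi-tissue family of clocks) is logarithmic
below an "adult age" parameter and linear above it, so that clock errors are
roughly proportional on the juvenile scale and additive on the adult scale.

This module applies *published-style* clocks; it never trains one.
Coefficient sets are consumed as small plain-text files (see
:func:`load_clock` for the format).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClockSpec",
    "BetaMatrix",
    "ClockFormatError",
    "MissingProbeError",
    "load_clock",
    "write_clock",
    "forward_transform",
    "inverse_transform",
    "predict_age",
    "extract_cpg_trajectory",
    "read_sample_sheet",
]

#: Beta values outside [0, 1] by more than this are rejected (they are most
#: likely logit-scale M-values); values within it are clipped.
BETA_TOLERANCE = 1e-6

TRANSFORMS = ("identity", "log-linear")


class ClockFormatError(ValueError):
    """A clock definition file is malformed; the message names the field."""


class MissingProbeError(KeyError):
    """Clock probes absent from a beta matrix under the ``error`` policy."""

    def __init__(self, probes):
        self.probes = list(probes)
        super().__init__(
            f"{len(self.probes)} clock probe(s) missing from beta matrix: "
            + ", ".join(map(str, self.probes[:10]))
            + ("..." if len(self.probes) > 10 else "")
        )


@dataclass(frozen=True)
class ClockSpec:
    """A named linear CpG clock.

    Parameters
    ----------
    name
        Clock identifier, recorded in every output row.
    intercept
        Intercept on the transformed-age scale (dimensionless for log-linear
        clocks, years for identity clocks).
    coefficients
        Mapping CpG probe ID -> weight per unit beta. Order is preserved.
    transform
        ``"identity"`` (the weighted sum already is an age in years) or
        ``"log-linear"`` (the sum is on the transformed scale and is mapped
        back to years with :func:`inverse_transform`).
    adult_age
        Pivot of the log-linear transform, in years. Required iff
        ``transform == "log-linear"``.
    output_units
        Units of the predicted age; informational.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    transform: str = "log-linear"
    adult_age: float | None = 20.0
    output_units: str = "years"

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ClockFormatError(
                f"transform must be one of {TRANSFORMS}, got {self.transform!r}"
            )
        if not self.coefficients:
            raise ClockFormatError("coefficients: clock has no probes")
        if self.transform == "log-linear":
            if self.adult_age is None:
                raise ClockFormatError(
                    "adult_age: required for transform=log-linear"
                )
            if not (self.adult_age > 0):
                raise ClockFormatError(f"adult_age: must be > 0, got {self.adult_age}")
        weights = np.asarray(list(self.coefficients.values()), dtype=float)
        if not np.all(np.isfinite(weights)):
            raise ClockFormatError("coefficients: non-finite weight")
        if not np.isfinite(self.intercept):
            raise ClockFormatError("intercept: non-finite")

    @property
    def probes(self) -> list[str]:
        return list(self.coefficients)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(list(self.coefficients.values()), dtype=float)


def load_clock(path) -> ClockSpec:
    """Parse a clock definition file.

    Format: ``#key=value`` header lines (``name``, ``intercept``,
    ``transform``, and ``adult_age`` when the transform is log-linear)
    followed by comma-separated ``probe,weight`` records, one per probe.
    """
    path = Path(path)
    header: dict[str, str] = {}
    coefficients: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise ClockFormatError(
                    f"{path}:{lineno}: header line without '=': {line!r}"
                )
            key, _, value = line[1:].partition("=")
            header[key.strip()] = value.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ClockFormatError(
                f"{path}:{lineno}: expected 'probe,weight', got {line!r}"
            )
        probe, weight_str = parts
        if probe in coefficients:
            raise ClockFormatError(f"{path}:{lineno}: duplicate probe {probe!r}")
        try:
            coefficients[probe] = float(weight_str)
        except ValueError as exc:
            raise ClockFormatError(
                f"{path}:{lineno}: weight for {probe!r} is not a number"
            ) from exc

    for required in ("name", "intercept", "transform"):
        if required not in header:
            raise ClockFormatError(f"{path}: missing header field '{required}'")
    transform = header["transform"]
    if transform == "log-linear" and "adult_age" not in header:
        raise ClockFormatError(
            f"{path}: adult_age header required for transform=log-linear"
        )
    try:
        intercept = float(header["intercept"])
    except ValueError as exc:
        raise ClockFormatError(f"{path}: intercept is not a number") from exc
    adult_age = None
    if "adult_age" in header:
        try:
            adult_age = float(header["adult_age"])
        except ValueError as exc:
            raise ClockFormatError(f"{path}: adult_age is not a number") from exc

    return ClockSpec(
        name=header["name"],
        intercept=intercept,
        coefficients=coefficients,
        transform=transform,
        adult_age=adult_age,
        output_units=header.get("output_units", "years"),
    )


def write_clock(clock: ClockSpec, path) -> None:
    """Serialize a :class:`ClockSpec` in the format :func:`load_clock` reads."""
    lines = [
        f"#name={clock.name}",
        f"#intercept={clock.intercept!r}",
        f"#transform={clock.transform}",
    ]
    if clock.adult_age is not None:
        lines.append(f"#adult_age={clock.adult_age!r}")
    lines.append(f"#output_units={clock.output_units}")
    lines += [f"{probe},{weight!r}" for probe, weight in clock.coefficients.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Age transform


def forward_transform(age, adult_age: float = 20.0):
    """Map age in years to the transformed scale of log-linear clocks.

    Piecewise: ``log(age + 1) - log(adult_age + 1)`` for ``age <= adult_age``
    and ``(age - adult_age) / (adult_age + 1)`` above. Continuous, strictly
    increasing, and zero at ``age == adult_age``. Defined for ``age > -1``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValueError("forward_transform: age must be > -1 year")
    if not adult_age > 0:
        raise ValueError("adult_age must be > 0")
    out = np.where(
        age <= adult_age,
        np.log1p(age) - math.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def inverse_transform(x, adult_age: float = 20.0):
    """Inverse of :func:`forward_transform`; defined on all reals.

    Negative transformed scores map to the logarithmic (juvenile) branch,
    positive ones to the linear (adult) branch; zero maps to ``adult_age``.
    """
    x = np.asarray(x, dtype=float)
    if not adult_age > 0:
        raise ValueError("adult_age must be > 0")
    out = np.where(
        x <= 0,
        np.expm1(x + math.log1p(adult_age)),
        adult_age + x * (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Beta matrices and sample sheets


@dataclass
class BetaMatrix:
    """Methylation fractions, probes x samples; ``NaN`` marks missing calls.

    Values outside [0, 1] by more than :data:`BETA_TOLERANCE` raise (a guard
    against logit-scale M-value input); values within tolerance are clipped.
    """

    values: pd.DataFrame

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        vals = df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            out_of_range = (vals < -BETA_TOLERANCE) | (vals > 1 + BETA_TOLERANCE)
        if np.any(out_of_range):
            n = int(np.sum(out_of_range))
            raise ValueError(
                f"{n} beta value(s) outside [0, 1] by more than {BETA_TOLERANCE}; "
                "are these M-values?"
            )
        self.values = df.astype(float).clip(0.0, 1.0)
        self.values.index.name = "probe"

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_csv(cls, path) -> "BetaMatrix":
        """Read a comma- or tab-separated probe x sample table.

        First column holds probe IDs, header row holds sample IDs;
        ``NA`` or empty cells are missing.
        """
        df = pd.read_csv(
            path, sep=None, engine="python", index_col=0, na_values=["NA"]
        )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="probe", na_rep="NA")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet with columns ``sample``, ``day``, ``replicate``."""
    sheet = pd.read_csv(path, sep=None, engine="python")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample", "day", "replicate"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.copy()
    sheet["sample"] = sheet["sample"].astype(str)
    sheet["day"] = sheet["day"].astype(float)
    if sheet["sample"].duplicated().any():
        raise ValueError("sample sheet has duplicate sample IDs")
    if (sheet["day"] < 0).any():
        raise ValueError("sample sheet has negative days")
    return sheet


# ---------------------------------------------------------------------------
# Prediction


def predict_age(
    clock: ClockSpec,
    betas: BetaMatrix,
    missing_policy: str = "error",
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply a clock to a beta matrix, one predicted age per sample.

    Parameters
    ----------
    missing_policy
        ``"error"``: every clock probe must be present and called in every
        sample. ``"impute_half"``: absent probes / missing calls are set to
        beta 0.5. ``"impute_reference"``: they are set to a user-supplied
        per-probe mean (``reference``, indexed by probe).

    Returns
    -------
    DataFrame with columns ``sample``, ``eage``, ``n_missing_probes``,
    ``clock``, one row per sample of ``betas``.
    """
    if missing_policy not in ("error", "impute_half", "impute_reference"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    probes = clock.probes
    sub = betas.values.reindex(index=probes)  # absent probes become all-NaN rows
    missing_mask = sub.isna()

    absent = [p for p in probes if p not in betas.values.index]
    if missing_policy == "error":
        bad = sorted(set(absent) | set(missing_mask.index[missing_mask.any(axis=1)]))
        if bad:
            raise MissingProbeError(bad)
    if len(absent) == len(probes):
        raise MissingProbeError(probes)

    all_missing = missing_mask.all(axis=0)
    if all_missing.any():
        bad_samples = list(sub.columns[all_missing])
        raise ValueError(
            f"sample(s) with no called clock probes: {bad_samples[:10]}"
        )

    if missing_policy == "impute_half":
        sub = sub.fillna(0.5)
    elif missing_policy == "impute_reference":
        if reference is None:
            raise ValueError("impute_reference requires a per-probe reference")
        ref = reference.reindex(probes)
        unref = [p for p, v in ref.items() if missing_mask.loc[p].any() and pd.isna(v)]
        if unref:
            raise MissingProbeError(unref)
        sub = sub.apply(lambda col: col.fillna(ref))

    scores = clock.intercept + clock.weights @ sub.to_numpy(dtype=float)
    if clock.transform == "log-linear":
        eage = inverse_transform(scores, clock.adult_age)
    else:
        eage = scores
    return pd.DataFrame(
        {
            "sample": sub.columns,
            "eage": np.atleast_1d(eage),
            "n_missing_probes": missing_mask.sum(axis=0).to_numpy(),
            "clock": clock.name,
        }
    )


def extract_cpg_trajectory(
    betas: BetaMatrix, probe: str, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-day mean and SD of a single probe's beta along the time course.

    Single CpGs known to track age (e.g. ELOVL2's cg16867657) are followed on
    the raw beta scale rather than through a calibrated clock. SD is the
    sample standard deviation (ddof=1), reported as 0 when n = 1.

    Returns a DataFrame with columns ``day``, ``mean``, ``sd``, ``n``,
    days sorted ascending.
    """
    if probe not in betas.values.index:
        raise MissingProbeError([probe])
    sheet = validate_sample_sheet(sheet)
    row = betas.values.loc[probe]
    merged = sheet.assign(beta=row.reindex(sheet["sample"]).to_numpy())
    merged = merged.dropna(subset=["beta"])
    grouped = merged.groupby("day")["beta"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out.loc[out["n"] == 1, "sd"] = 0.0
    out["n"] = out["n"].astype(int)
    return out.sort_values("day", ignore_index=True)
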