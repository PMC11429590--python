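"""Reading, validation and descriptive summary of six-generation phenotype data.

Input is a plain CSV with columns ``generation`` and ``value`` (an
optional ``cross`` column selects one cross from a pooled file).  The
six generations of a biparental design — the parents P1 and P2, their
hybrid F1, the selfed F2 and the two first backcrosses BC1P1 (F1 x P1)
and BC1P2 (F1 x P2) — must all be present.

Summaries report n, min, max, mean, the n-1 standard deviation and
variance, the coefficient of variation 100*SD/mean, the adjusted
Fisher-Pearson skewness g1*sqrt(n(n-1))/(n-2) and the bias-corrected
*excess* kurtosis — the conventions of the major commercial statistics
packages, so values are directly comparable with published tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genmodels import GENERATIONS

__all__ = [
    "GenerationSample",
    "SixGenDataset",
    "SummaryRow",
    "IncompleteDesignError",
    "PhenotypeParseError",
    "read_dataset",
    "summarize",
    "summary_table",
    "write_dataset",
]


class IncompleteDesignError(ValueError):
    """One or more of the six generations is missing from the input."""


class PhenotypeParseError(ValueError):
    """A phenotype value could not be parsed as a number."""


@dataclass(frozen=True)
class GenerationSample:
    """Phenotype vector of one generation (trait units, e.g. mg/100 g)."""

    generation: str
    values: np.ndarray
    cross_id: str = ""

    def __post_init__(self):
        if self.generation not in GENERATIONS:
            raise ValueError(
                f"generation must be one of {GENERATIONS}, got {self.generation!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError(
                f"{self.generation}: need at least 2 finite values, got {vals.size}")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.generation}: non-finite phenotype values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SixGenDataset:
    """A complete six-generation dataset for one cross."""

    cross_id: str
    samples: Mapping[str, GenerationSample]

    def __post_init__(self):
        missing = [g for g in GENERATIONS if g not in self.samples]
        if missing:
            raise IncompleteDesignError(
                "incomplete design: missing generation(s) " + ", ".join(missing))

    def __getitem__(self, generation: str) -> GenerationSample:
        return self.samples[generation]

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.samples.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cross": self.cross_id, "generation": g, "value": v}
            for g in GENERATIONS
            for v in self.samples[g].values
        ]
        return pd.DataFrame(rows)

    def shifted(self, c: float) -> "SixGenDataset":
        return SixGenDataset(self.cross_id, {
            g: GenerationSample(g, s.values + c, s.cross_id)
            for g, s in self.samples.items()})

    def scaled(self, s: float) -> "SixGenDataset":
        return SixGenDataset(self.cross_id, {
            g: GenerationSample(g, smp.values * s, smp.cross_id)
            for g, smp in self.samples.items()})


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics of one generation sample."""

    generation: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    variance: float
    cv_percent: float
    skewness: float
    kurtosis: float


_CANON = {g.upper(): g for g in GENERATIONS}


def _canon_generation(label: object) -> str | None:
    return _CANON.get(str(label).strip().upper())


def read_dataset(path, cross_id: str = "", sep: str = ",") -> SixGenDataset:
    """Read a six-generation phenotype CSV into a validated dataset.

    Parameters
    ----------
    path : path-like or file-like
        CSV with a header and columns ``generation`` and ``value``
        (generation labels are matched case-insensitively).  An optional
        ``cross`` column is filtered on ``cross_id`` when given.
    cross_id : str
        Label attached to the dataset (and filter key for pooled files).
    sep : str
        Field separator; pass ``"\\t"`` for TSV.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("generation", "value"):
        if col not in df.columns:
            raise ValueError(f"input must have a {col!r} column (header required)")
    if "cross" in df.columns and cross_id:
        df = df[df["cross"].str.strip() == cross_id]
        if df.empty:
            raise ValueError(f"no rows for cross {cross_id!r}")
    parsed = pd.to_numeric(df["value"], errors="coerce")
    bad = parsed.isna() & df["value"].notna() | df["value"].isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise PhenotypeParseError(
            f"non-numeric phenotype value {df['value'].get(bad.idxmax())!r} "
            f"at line {row}")
    gens = df["generation"].map(_canon_generation)
    if gens.isna().any():
        bad_label = df["generation"][gens.isna()].iloc[0]
        raise ValueError(
            f"unknown generation label {bad_label!r}; expected one of {GENERATIONS}")
    samples = {}
    for g in GENERATIONS:
        vals = parsed[gens == g].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        if vals.size < 2:
            raise ValueError(f"generation {g} has n={vals.size} < 2")
        samples[g] = GenerationSample(g, vals, cross_id)
    return SixGenDataset(cross_id, samples)


def write_dataset(dataset: SixGenDataset, path, sep: str = ",") -> None:
    """Write a dataset in the CSV dialect :func:`read_dataset` accepts."""
    df = dataset.to_frame()
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, sep=sep, index=False)
    else:
        df.to_csv(path, sep=sep, index=False)


def summarize(sample: GenerationSample | Iterable[float],
              generation: str = "") -> SummaryRow:
    """Descriptive statistics of one generation.

    The standard deviation uses the n-1 denominator; skewness and
    kurtosis use the bias-corrected (sample-size adjusted) formulas and
    kurtosis is excess kurtosis (0 for a normal distribution).  With a
    constant sample both shape statistics are undefined (NaN); kurtosis
    additionally requires n >= 4 and skewness n >= 3.
    """
    if isinstance(sample, GenerationSample):
        values, generation = sample.values, sample.generation
    else:
        values = np.asarray(list(sample), dtype=float)
        if values.size < 2:
            raise ValueError("need at least 2 values")
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    constant = sd == 0.0
    skew = (np.nan if constant or n < 3
            else float(stats.skew(values, bias=False)))
    kurt = (np.nan if constant or n < 4
            else float(stats.kurtosis(values, bias=False)))
    return SummaryRow(
        generation=generation,
        n=int(n),
        min=float(np.min(values)),
        max=float(np.max(values)),
        mean=mean,
        sd=sd,
        variance=sd * sd,
        cv_percent=100.0 * sd / mean,
        skewness=skew,
        kurtosis=kurt,
    )


def summary_table(dataset: SixGenDataset, round_to: int | None = 2) -> pd.DataFrame:
    """Per-generation summary in published-table column order."""
    rows = []
    for g in GENERATIONS:
        r = summarize(dataset[g])
        rows.append({
            "generation": g, "n": r.n, "min": r.min, "max": r.max,
            "mean": r.mean, "sd": r.sd, "variance": r.variance,
            "cv_percent": r.cv_percent, "skewness": r.skewness,
            "kurtosis": r.kurtosis,
        })
    df = pd.DataFrame(rows)
    if round_to is not None:
        num = df.columns.drop(["generation", "n"])
        df[num] = df[num].round(round_to)
    return df
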