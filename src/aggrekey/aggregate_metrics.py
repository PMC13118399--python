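"""Soil-aggregate stability and carbon-partitioning metrics.

Wet sieving partitions a soil sample into size classes; each class ``i`` has
an oven-dry mass ``m_i`` (g) and an organic-carbon concentration ``c_i``
(g C kg^-1 of fraction).  From these this module computes, per sample:

* the mass distribution ``w_i = m_i / sum_j m_j`` (reported in %),
* the macroaggregate mass share ``R0.25-mass`` — the percentage of total
  soil mass held in classes coarser than 0.25 mm,
* the mean weight diameter ``MWD = sum_i xbar_i * w_i`` (mm), where
  ``xbar_i`` is the representative mean diameter of class ``i``,
* the carbon distribution — the share of the total aggregate-held C stock
  ``m_i * c_i`` residing in each class (in %), and
* the macroaggregate carbon share ``R0.25-SOC``.

Treatment-level summaries (means, SDs) and percent contrasts between named
treatment sets mirror how such experiments are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered, non-overlapping size classes covering (0, upper sieve].

    ``bounds`` are (lower, upper) sieve openings in mm, coarsest first;
    ``mean_diameters`` are the representative diameters xbar_i used by MWD.
    The default scheme is the conventional four-class wet-sieving set with
    midpoint representative diameters, the open top class being bounded by
    the 8 mm pre-sieving mesh.
    """

    labels: tuple[str, ...] = (">2mm", "0.25-2mm", "0.053-0.25mm", "<0.053mm")
    bounds: tuple[tuple[float, float], ...] = (
        (2.0, 8.0), (0.25, 2.0), (0.053, 0.25), (0.0, 0.053))
    mean_diameters: tuple[float, ...] = (5.0, 1.125, 0.1515, 0.0265)
    macro_cutoff: float = 0.25

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.bounds) == len(self.mean_diameters) == n):
            raise ValueError("scheme fields must have equal length")
        for (lo, hi), d in zip(self.bounds, self.mean_diameters):
            if not lo < hi:
                raise ValueError(f"invalid class bounds ({lo}, {hi})")
            if not lo <= d <= hi:
                raise ValueError(
                    f"mean diameter {d} outside class bounds ({lo}, {hi})")
        for (lo, _), (_, hi_next) in zip(self.bounds, self.bounds[1:]):
            if not np.isclose(lo, hi_next):
                raise ValueError("classes must be ordered coarse-to-fine and contiguous")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def macro_mask(self) -> np.ndarray:
        """Boolean mask of classes lying entirely above the macro cutoff."""
        return np.array([lo >= self.macro_cutoff for lo, _ in self.bounds])


DEFAULT_SCHEME = SizeClassScheme()


@dataclass
class AggregateProfile:
    """Per-sample wet-sieving result: fraction masses, per-fraction SOC
    concentration, and bulk-soil SOC."""

    sample_id: str
    masses: np.ndarray            # g per class
    soc_conc: np.ndarray          # g C kg^-1 of fraction
    soc_bulk: float               # g C kg^-1 bulk soil
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.soc_conc = np.asarray(self.soc_conc, dtype=float)
        n = self.scheme.n_classes
        if self.masses.shape != (n,) or self.soc_conc.shape != (n,):
            raise ValueError(
                f"profile {self.sample_id!r}: expected {n} masses and {n} "
                f"concentrations, got {self.masses.shape} / {self.soc_conc.shape}")
        if np.any(np.isnan(self.masses)) or np.any(np.isnan(self.soc_conc)):
            raise ValueError(f"profile {self.sample_id!r}: NaN in required inputs")
        if np.any(self.masses < 0) or np.any(self.soc_conc < 0):
            raise ValueError(f"profile {self.sample_id!r}: negative mass or SOC")
        if self.masses.sum() <= 0:
            raise ValueError(f"profile {self.sample_id!r}: all fraction masses zero")


def mass_proportions(profile: AggregateProfile) -> np.ndarray:
    """Mass percentage of each size class (sums to 100)."""
    total = profile.masses.sum()
    if total <= 0:
        raise ValueError("total fraction mass is zero")
    return profile.masses / total * 100.0


def macroaggregate_share(per_class_percent: Sequence[float],
                         scheme: SizeClassScheme = DEFAULT_SCHEME) -> float:
    """Share (%) of a per-class percentage vector lying in >0.25 mm classes.

    Applied to mass proportions this is R0.25-mass; applied to the carbon
    distribution it is R0.25-SOC.  The vector is renormalized by its own sum
    so rows that total 100.00 reproduce printed table identities exactly.
    """
    v = np.asarray(per_class_percent, dtype=float)
    if v.shape != (scheme.n_classes,):
        raise ValueError("per-class vector does not match scheme")
    s = v.sum()
    if s <= 0:
        raise ValueError("per-class vector sums to zero")
    return float(v[scheme.macro_mask].sum() / s * 100.0)


def r025_mass(profile: AggregateProfile) -> float:
    """Percentage of total soil mass in >0.25 mm macroaggregates."""
    return macroaggregate_share(mass_proportions(profile), profile.scheme)


def mwd(profile: AggregateProfile,
        scheme: SizeClassScheme | None = None) -> float:
    """Mean weight diameter (mm): mass-fraction-weighted mean of xbar_i."""
    scheme = scheme or profile.scheme
    if scheme.n_classes != len(profile.masses):
        raise ValueError("scheme class count does not match profile")
    w = profile.masses / profile.masses.sum()
    return float(np.dot(scheme.mean_diameters, w))


def c_stocks(profile: AggregateProfile) -> np.ndarray:
    """Carbon stock per class, mass x concentration (g C per sieved sample)."""
    return profile.masses * profile.soc_conc / 1000.0


def c_distribution(profile: AggregateProfile) -> np.ndarray:
    """Share (%) of the total aggregate-held C stock in each class."""
    stocks = c_stocks(profile)
    total = stocks.sum()
    if total <= 0:
        raise ValueError("all per-class carbon stocks are zero")
    return stocks / total * 100.0


def r025_soc(profile: AggregateProfile) -> float:
    """Percentage of aggregate-held organic C in >0.25 mm macroaggregates."""
    return macroaggregate_share(c_distribution(profile), profile.scheme)


def sample_metrics(profiles: Iterable[AggregateProfile]) -> pd.DataFrame:
    """Per-sample metric table: mass %, R0.25-mass, MWD, C %, R0.25-SOC.

    Column names: ``mass_pct:<label>``, ``c_pct:<label>``, ``r025_mass``,
    ``mwd``, ``r025_soc``, ``soc_bulk``.
    """
    rows = {}
    for p in profiles:
        mp = mass_proportions(p)
        cd = c_distribution(p)
        row: dict[str, float] = {}
        for lab, v in zip(p.scheme.labels, mp):
            row[f"mass_pct:{lab}"] = v
        row["r025_mass"] = macroaggregate_share(mp, p.scheme)
        row["mwd"] = mwd(p)
        for lab, v in zip(p.scheme.labels, p.soc_conc):
            row[f"soc_conc:{lab}"] = v
        for lab, v in zip(p.scheme.labels, cd):
            row[f"c_pct:{lab}"] = v
        row["r025_soc"] = macroaggregate_share(cd, p.scheme)
        row["soc_bulk"] = p.soc_bulk
        rows[p.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def treatment_summary(metrics: pd.DataFrame, design) -> pd.DataFrame:
    """Per-treatment mean and SD of every metric column.

    ``design`` is a :class:`~aggrekey.io_config.StudyDesign`; every treatment
    needs >= 2 replicates.  Returns a frame indexed by treatment with a
    two-level column index (metric, {"mean", "sd"}).
    """
    trt = design.treatment_of(metrics.index)
    grouped = metrics.groupby(trt)
    counts = grouped.size()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"treatments with fewer than 2 replicates: {bad}")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
    out.index.name = "treatment"
    return out


def group_contrast(treatment_means: pd.Series,
                   set_a: Sequence[str], set_b: Sequence[str]) -> float:
    """Percent difference of treatment-set means: 100*(mean_A/mean_B - 1).

    ``treatment_means`` holds one (mean) value per treatment; each set's
    value is the unweighted mean over its member treatments.
    """
    for t in list(set_a) + list(set_b):
        if t not in treatment_means.index:
            raise ValueError(f"unknown treatment in contrast request: {t!r}")
    a = treatment_means.loc[list(set_a)].mean()
    b = treatment_means.loc[list(set_b)].mean()
    if b == 0:
        raise ValueError("reference set mean is zero")
    return float(100.0 * (a / b - 1.0))


def contrast_table(metrics: pd.DataFrame, design,
                   contrasts: Mapping[str, tuple[Sequence[str], Sequence[str]]]
                   ) -> pd.DataFrame:
    """Evaluate named contrasts for every metric column.

    ``contrasts`` maps a contrast name to (set_a, set_b) treatment tuples.
    Returns contrast-percent values, one row per contrast, one column per
    metric.
    """
    trt = design.treatment_of(metrics.index)
    means = metrics.groupby(trt).mean()
    rows = {}
    for name, (a, b) in contrasts.items():
        rows[name] = {col: group_contrast(means[col], a, b) for col in means}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "contrast"
    return out
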