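"""Synthetic study generator with planted, recoverable ground truth.

Emulates the data structure the pipeline assumes: seven cropping
treatments x three replicates, three marker sets (bacteria, non-AMF fungi,
AMF), and per-sample wet-sieving profiles whose per-treatment targets
default to the field study's published means and SDs.

Genus abundances follow a log-normal/multinomial composition model.  Each
planted module ``m`` has a latent per-sample activity
``a_m ~ Normal(mu_m(treatment), 1)``; a member genus's log-abundance is
``baseline + loading_m * a_m + Normal(0, sigma_member)`` while non-members
receive independent noise.  The loading is derived from the requested
within-module correlation ``rho`` of member log-abundances
(``loading = sigma_member * sqrt(rho / (1 - rho))``).  Per-sample
compositions are softmax-scaled per kingdom and sampled multinomially at a
depth drawn uniformly from the configured range, so rarefaction tests have
exact depth control.

Aggregate profiles couple the planted modules to the carbon responses:
the mass proportion of a coupled size class is perturbed by
``beta * a_m`` before the four-class vector is renormalized to 100%, so a
module's activity shifts both the mass and the carbon share of its class
with an interpretable sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .aggregate_metrics import AggregateProfile, SizeClassScheme
from .community_ecology import KINGDOM_PREFIXES, AbundanceTable
from .io_config import StudyDesign


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: members, target within-module correlation of
    member log-abundances, and per-treatment mean activity."""

    name: str
    members: tuple[str, ...]
    rho: float
    activity_means: Mapping[str, float]

    def loading(self, member_noise_sd: float) -> float:
        if not 0 <= self.rho < 1:
            raise ValueError("within-module correlation must be in [0, 1)")
        return member_noise_sd * np.sqrt(self.rho / (1.0 - self.rho))


@dataclass(frozen=True)
class CouplingSpec:
    """Links one module's activity to the mass share of one size class."""

    module: str
    size_class: str
    beta: float      # percentage points of mass share per activity unit


def _default_modules() -> tuple[ModuleSpec, ...]:
    # Three treatment-responsive clusters with weakly collinear activity
    # patterns, so the planted partition stays identifiable: strongly
    # anti-correlated patterns would bridge modules with |rho|>threshold
    # edges and walktrap would merge them.
    # the coupled module gets a wider treatment spread: its members must be
    # detectably treatment-responsive at n = 3 replicates despite the unit
    # within-treatment activity noise
    g2_high = {"MM": 0.5, "MI1": 0.5, "MI2": 0.5,
               "MI3": 2.3, "MI4": 2.3, "MI5": 2.3, "MI6": 2.3}
    mi6_high = {t: (1.8 if t == "MI6" else 0.6) for t in reference.TREATMENTS}
    mono_high = {t: (1.8 if t in ("MM", "MI1") else 0.6)
                 for t in reference.TREATMENTS}

    def members(b0: int, f0: int, a0: int) -> tuple[str, ...]:
        return (tuple(f"B_g{b0 + i:03d}" for i in range(7))
                + tuple(f"F_g{f0 + i:03d}" for i in range(3))
                + tuple(f"AMF_g{a0 + i:03d}" for i in range(2)))

    return (
        ModuleSpec("M1", members(1, 1, 1), rho=0.9, activity_means=g2_high),
        ModuleSpec("M2", members(8, 4, 3), rho=0.9, activity_means=mi6_high),
        ModuleSpec("M3", members(15, 7, 5), rho=0.9, activity_means=mono_high),
    )


@dataclass
class SimSpec:
    """Full description of one synthetic study."""

    treatments: tuple[str, ...] = reference.TREATMENTS
    replicates: int = 3
    genus_counts: Mapping[str, int] = field(
        default_factory=lambda: {"bacteria": 100, "nonamf": 60, "amf": 40})
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    couplings: tuple[CouplingSpec, ...] = (
        CouplingSpec("M1", "0.25-2mm", beta=8.0),)
    member_noise_sd: float = 0.3
    independent_noise_sd: float = 1.0
    baseline_sd: float = 1.0
    # module members draw their baselines from a tighter, slightly elevated
    # distribution: a planted module is a coherent cluster of comparably
    # abundant genera, and an extremely skewed within-module abundance
    # split would reduce the cumulative-abundance prefix to one genus
    member_baseline_mean: float = 0.3
    member_baseline_sd: float = 0.3
    mass_targets: pd.DataFrame = field(
        default_factory=lambda: reference.MASS_PROPORTION_MEAN.copy())
    mass_noise_sd: pd.DataFrame = field(
        default_factory=lambda: reference.MASS_PROPORTION_SD.copy())
    conc_targets: pd.DataFrame = field(
        default_factory=lambda: reference.SOC_CONCENTRATION_MEAN.copy())
    conc_noise_sd: pd.DataFrame = field(
        default_factory=lambda: reference.SOC_CONCENTRATION_SD.copy())
    bulk_noise_sd: float = 0.5
    total_mass_g: float = 60.0
    depth_range: tuple[int, int] = (20_000, 30_000)
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)

    def validate(self) -> "SimSpec":
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        for k in self.genus_counts:
            if k not in KINGDOM_PREFIXES:
                raise ValueError(f"unknown kingdom {k!r}")
        known = set(self.genus_ids_flat())
        names = set()
        for mod in self.modules:
            if mod.name in names:
                raise ValueError(f"duplicate module name {mod.name!r}")
            names.add(mod.name)
            unknown = set(mod.members) - known
            if unknown:
                raise ValueError(
                    f"module {mod.name!r} references unknown genera: {sorted(unknown)}")
            if not 0 <= mod.rho < 1:
                raise ValueError("module correlation must be in [0, 1)")
            for t in self.treatments:
                if mod.activity_means.get(t, 0.0) <= 0:
                    raise ValueError(
                        f"module {mod.name!r}: activity multiplier for {t} must be > 0")
        for c in self.couplings:
            if c.module not in names:
                raise ValueError(f"coupling references unknown module {c.module!r}")
            if c.size_class not in self.scheme.labels:
                raise ValueError(f"coupling references unknown class {c.size_class!r}")
        row_sums = self.mass_targets.loc[list(self.treatments)].sum(axis=1)
        if not np.allclose(row_sums, 100.0, atol=0.5):
            raise ValueError("mass-target rows must sum to 100 +- 0.5%")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ValueError("depth range must be positive and ordered")
        return self

    def genus_ids(self, kingdom: str) -> list[str]:
        prefix = KINGDOM_PREFIXES[kingdom]
        return [f"{prefix}g{i + 1:03d}" for i in range(self.genus_counts[kingdom])]

    def genus_ids_flat(self) -> list[str]:
        return [g for k in self.genus_counts for g in self.genus_ids(k)]

    def design(self) -> StudyDesign:
        return StudyDesign.balanced(self.treatments, self.replicates)


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic tables."""

    design: StudyDesign
    membership: dict[str, tuple[str, ...]]          # module -> members
    activities: pd.DataFrame                        # modules x samples
    couplings: tuple[CouplingSpec, ...]

    def coupled_modules(self) -> list[str]:
        return [c.module for c in self.couplings]

    def to_dict(self) -> dict:
        return {
            "membership": {m: list(v) for m, v in self.membership.items()},
            "activities": {m: self.activities.loc[m].to_dict()
                           for m in self.activities.index},
            "couplings": [{"module": c.module, "size_class": c.size_class,
                           "beta": c.beta} for c in self.couplings],
        }


def simulate_abundances(spec: SimSpec, seed: int
                        ) -> tuple[dict[str, AbundanceTable], SimTruth]:
    """Generate the three genus count tables plus the planted truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    design = spec.design()
    samples = design.samples
    trt = design.treatment_of(samples)
    n = len(samples)

    activities = pd.DataFrame(
        {m.name: rng.normal([m.activity_means[t] for t in trt], 1.0)
         for m in spec.modules}, index=samples).T
    activities.index.name = "module"

    member_of: dict[str, ModuleSpec] = {}
    for mod in spec.modules:
        for g in mod.members:
            if g in member_of:
                raise ValueError(f"genus {g} belongs to more than one module")
            member_of[g] = mod

    tables: dict[str, AbundanceTable] = {}
    for kingdom in spec.genus_counts:
        genera = spec.genus_ids(kingdom)
        baseline = rng.normal(0.0, spec.baseline_sd, len(genera))
        member_baseline = rng.normal(spec.member_baseline_mean,
                                     spec.member_baseline_sd, len(genera))
        is_member = np.array([g in member_of for g in genera])
        baseline = np.where(is_member, member_baseline, baseline)
        log_ab = np.tile(baseline[:, None], (1, n))
        for i, g in enumerate(genera):
            mod = member_of.get(g)
            if mod is not None:
                loading = mod.loading(spec.member_noise_sd)
                log_ab[i] += (loading * activities.loc[mod.name].to_numpy()
                              + rng.normal(0.0, spec.member_noise_sd, n))
            else:
                log_ab[i] += rng.normal(0.0, spec.independent_noise_sd, n)
        # softmax per sample, multinomial at a uniform random depth
        z = np.exp(log_ab - log_ab.max(axis=0))
        probs = z / z.sum(axis=0)
        counts = np.empty_like(log_ab, dtype=np.int64)
        for j in range(n):
            depth = int(rng.integers(spec.depth_range[0],
                                     spec.depth_range[1] + 1))
            counts[:, j] = rng.multinomial(depth, probs[:, j])
        tables[kingdom] = AbundanceTable(
            data=pd.DataFrame(counts, index=genera, columns=samples),
            kingdom=kingdom)

    truth = SimTruth(design=design,
                     membership={m.name: m.members for m in spec.modules},
                     activities=activities, couplings=spec.couplings)
    return tables, truth


def simulate_aggregates(spec: SimSpec, truth: SimTruth,
                        seed: int) -> list[AggregateProfile]:
    """Generate per-sample wet-sieving profiles coupled to module activity."""
    spec.validate()
    rng = np.random.default_rng(seed)
    design = truth.design
    labels = list(spec.scheme.labels)
    missing = [s for s in design.samples
               if s not in truth.activities.columns]
    if missing:
        raise ValueError(f"activities missing for samples: {missing}")

    profiles = []
    for sample in design.samples:
        t = design.treatment_of([sample]).iloc[0]
        target = spec.mass_targets.loc[t, labels].to_numpy(dtype=float)
        sd = spec.mass_noise_sd.loc[t, labels].to_numpy(dtype=float)
        shift = np.zeros(len(labels))
        for c in truth.couplings:
            j = labels.index(c.size_class)
            shift[j] += c.beta * truth.activities.loc[c.module, sample]
        for attempt in range(100):
            raw = target + shift + rng.normal(0.0, sd)
            if np.all((raw >= 0.0) & (raw <= 100.0)):
                break
        else:
            raise ValueError("infeasible spec: mass proportions out of range "
                             "after 100 redraws")
        proportions = raw / raw.sum() * 100.0

        conc_target = spec.conc_targets.loc[t, labels].to_numpy(dtype=float)
        conc_sd = spec.conc_noise_sd.loc[t, labels].to_numpy(dtype=float)
        for attempt in range(100):
            conc = conc_target + rng.normal(0.0, conc_sd)
            if np.all(conc > 0):
                break
        else:
            raise ValueError("infeasible spec: negative SOC concentration "
                             "after 100 redraws")

        masses = proportions / 100.0 * spec.total_mass_g
        bulk = float(np.dot(proportions / 100.0, conc)
                     + rng.normal(0.0, spec.bulk_noise_sd))
        profiles.append(AggregateProfile(
            sample_id=sample, masses=masses, soc_conc=conc,
            soc_bulk=max(bulk, 0.0), scheme=spec.scheme))
    return profiles
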