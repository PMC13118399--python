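"""Tabular I/O, run configuration and logging for the pipeline.

File dialect: UTF-8 TSV, '.' decimal separator, no thousands separators.
Genus identifiers must match ``^[A-Za-z0-9_.-]+$`` and are prefixed by
kingdom (``B_`` / ``F_`` / ``AMF_``) on read so that ids are globally
unique when the three marker sets are pooled into one network.

Every output file carries the configuration hash and the seed on a leading
comment line, so two runs with identical config + seed are byte-identical
and self-describing.  Missing values are never imputed: any NaN in a
required input is a hard error, because the downstream statistics assume a
complete treatments x replicates design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .aggregate_metrics import AggregateProfile, SizeClassScheme
from .community_ecology import KINGDOM_PREFIXES, AbundanceTable

logger = logging.getLogger("aggrekey")

GENUS_ID_RE = re.compile(r"^[A-Za-z0-9_.-]+$")

MASS_COLUMNS = ("mass_gt2mm", "mass_025_2mm", "mass_0053_025mm", "mass_lt0053mm")
SOC_COLUMNS = ("soc_gt2mm", "soc_025_2mm", "soc_0053_025mm", "soc_lt0053mm")
BULK_COLUMN = "soc_bulk"


class StudyDesign:
    """Sample -> treatment mapping for a randomized design.

    Holds one row per sample with its treatment, replicate number and an
    optional group label.  Sample ids must be unique; significance testing
    downstream requires >= 2 replicates per treatment.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "treatment", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {list(dups)}")
        if (frame["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_table(cls, path: str | Path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def balanced(cls, treatments: Iterable[str], replicates: int,
                 groups: dict[str, str] | None = None) -> "StudyDesign":
        """Build the conventional treatments x replicates design with sample
        ids ``<treatment>_<replicate>``."""
        rows = [{"sample_id": f"{t}_{r}", "treatment": t, "replicate": r,
                 "group": (groups or {}).get(t, "")}
                for t in treatments for r in range(1, replicates + 1)]
        return cls(pd.DataFrame(rows))

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.frame["treatment"]))

    def treatment_of(self, sample_ids) -> pd.Series:
        mapping = self.frame.set_index("sample_id")["treatment"]
        missing = [s for s in sample_ids if s not in mapping.index]
        if missing:
            raise KeyError(f"samples absent from design: {missing}")
        return mapping.loc[list(sample_ids)]

    def replicate_counts(self) -> pd.Series:
        return self.frame.groupby("treatment").size()

    def to_table(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the study defaults."""

    correlation_threshold: float = 0.7   # |rho| for a network edge
    edge_alpha: float = 0.05             # BH-adjusted p for a network edge
    dominant_cutoff: float = 0.001       # mean relative abundance (0.1%)
    major_module_fraction: float = 0.10  # node share for a "major" module
    keystone_abundance_fraction: float = 0.75  # cumulative-abundance prefix
    duncan_alpha: float = 0.05
    keystone_alpha: float = 0.05
    permanova_permutations: int = 999
    walktrap_steps: int = 4
    rf_trees: int = 500
    rf_permutations: int = 999
    rf_alpha: float = 0.05
    plspm_tol: float = 1e-7
    plspm_max_iter: int = 300
    plspm_scheme: str = "path"
    bootstrap_samples: int = 0           # 0 disables path bootstrapping
    rarefaction_depth: int | str = "min"
    seed: int = 0
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)

    def validate(self) -> "RunConfig":
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation threshold must be in (0, 1]")
        for name in ("edge_alpha", "dominant_cutoff", "duncan_alpha",
                     "keystone_alpha", "rf_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("major_module_fraction", "keystone_abundance_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.permanova_permutations < 99 or self.rf_permutations < 1:
            raise ValueError("permutation counts too small")
        if self.walktrap_steps < 1 or self.rf_trees < 1:
            raise ValueError("counts must be positive")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scheme"] = {"labels": list(self.scheme.labels),
                       "bounds": [list(b) for b in self.scheme.bounds],
                       "mean_diameters": list(self.scheme.mean_diameters),
                       "macro_cutoff": self.scheme.macro_cutoff}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scheme_raw = raw.pop("scheme", None)
        kwargs = dict(raw)
        if scheme_raw is not None:
            kwargs["scheme"] = SizeClassScheme(
                labels=tuple(scheme_raw["labels"]),
                bounds=tuple(tuple(b) for b in scheme_raw["bounds"]),
                mean_diameters=tuple(scheme_raw["mean_diameters"]),
                macro_cutoff=scheme_raw.get("macro_cutoff", 0.25))
        return cls(**kwargs).validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_abundance_table(path: str | Path, kingdom: str,
                         design: StudyDesign | None = None) -> AbundanceTable:
    """Read a tab-separated genus x sample matrix.

    First column: genus identifiers; header row: sample ids; cells:
    non-negative numbers.  Genus ids are prefixed by kingdom (``B_`` /
    ``F_`` / ``AMF_``) unless already so prefixed.  With ``design`` given,
    the sample set must match it exactly.
    """
    if kingdom not in KINGDOM_PREFIXES:
        raise ValueError(f"unknown kingdom {kingdom!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    prefix = KINGDOM_PREFIXES[kingdom]
    for g in df.index:
        bare = g[len(prefix):] if g.startswith(prefix) else g
        if not GENUS_ID_RE.match(bare):
            raise ValueError(f"invalid genus id {g!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate genus id within kingdom: {dups}")
    vals = df.to_numpy()
    if np.any(pd.isna(vals)):
        raise ValueError("missing abundance value")
    if (vals < 0).any():
        raise ValueError("negative abundance")
    df.index = [g if g.startswith(prefix) else prefix + g for g in df.index]
    if design is not None:
        missing = sorted(set(design.samples) - set(df.columns))
        extra = sorted(set(df.columns) - set(design.samples))
        if missing or extra:
            raise ValueError(
                f"sample mismatch vs design: missing={missing} extra={extra}")
        df = df[design.samples]
    return AbundanceTable(data=df, kingdom=kingdom)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "genus"
    df.to_csv(path, sep="\t")


def read_aggregate_profiles(path: str | Path, design: StudyDesign,
                            scheme: SizeClassScheme | None = None
                            ) -> list[AggregateProfile]:
    """Read per-sample wet-sieving rows.

    Required columns: ``sample_id``, the four fraction masses (g)
    ``mass_gt2mm, mass_025_2mm, mass_0053_025mm, mass_lt0053mm``, the four
    fraction SOC concentrations (g C kg^-1) ``soc_gt2mm, ...`` and the bulk
    concentration ``soc_bulk``.
    """
    scheme = scheme or SizeClassScheme()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("sample_id",) + MASS_COLUMNS + SOC_COLUMNS + (BULK_COLUMN,)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"aggregate table missing columns: {missing}")
    if df[list(MASS_COLUMNS + SOC_COLUMNS + (BULK_COLUMN,))].isna().any().any():
        raise ValueError("missing value in aggregate table")
    known = set(design.samples)
    unknown = [s for s in df["sample_id"] if s not in known]
    if unknown:
        raise ValueError(f"samples absent from design: {unknown}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(AggregateProfile(
            sample_id=str(row["sample_id"]),
            masses=row[list(MASS_COLUMNS)].to_numpy(dtype=float),
            soc_conc=row[list(SOC_COLUMNS)].to_numpy(dtype=float),
            soc_bulk=float(row[BULK_COLUMN]),
            scheme=scheme))
    return profiles


def write_aggregate_profiles(profiles: Iterable[AggregateProfile],
                             path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict[str, Any] = {"sample_id": p.sample_id}
        row.update(zip(MASS_COLUMNS, p.masses))
        row.update(zip(SOC_COLUMNS, p.soc_conc))
        row[BULK_COLUMN] = p.soc_bulk
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ResultBundle:
    """Completed pipeline artifacts routed to :func:`write_results`."""

    config: RunConfig
    metrics: pd.DataFrame | None = None            # per-sample aggregate metrics
    summary: pd.DataFrame | None = None            # per-treatment mean/SD
    letters: pd.DataFrame | None = None            # Duncan letters per metric
    contrasts: pd.DataFrame | None = None
    edges: pd.DataFrame | None = None              # network edge list
    modules: pd.DataFrame | None = None            # genus -> module table
    keystone: pd.DataFrame | None = None           # module correlation table
    crucial: pd.DataFrame | None = None            # genus importance table
    plspm: dict[str, Any] | None = None
    ordination: dict[str, pd.DataFrame] = field(default_factory=dict)
    # per-kingdom PCoA coordinates; frame.attrs["variance_explained"] holds
    # the leading-axis fractions written into the header comment
    extra: dict[str, Any] = field(default_factory=dict)


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_results(out_dir: str | Path, bundle: ResultBundle) -> dict[str, Path]:
    """Write the deterministic artifact set for a pipeline run.

    Empty tables are written header-only; a NaN path coefficient in the
    path-model payload is rejected as an unconverged model.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    written: dict[str, Path] = {}

    tables = {
        "aggregate_metrics.tsv": bundle.metrics,
        "summary.tsv": bundle.summary,
        "anova_letters.tsv": bundle.letters,
        "contrasts.tsv": bundle.contrasts,
        "network_edges.tsv": bundle.edges,
        "modules.tsv": bundle.modules,
        "keystone.tsv": bundle.keystone,
        "crucial_genera.tsv": bundle.crucial,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / name
        _write_tsv(df, path, cfg, index=df.index.name is not None)
        written[name] = path

    for kingdom, coords in bundle.ordination.items():
        path = out / f"pcoa_{kingdom}.tsv"
        frac = coords.attrs.get("variance_explained", ())
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_stamp(cfg))
            fh.write("# variance_explained\t"
                     + "\t".join(f"{v:.6f}" for v in frac) + "\n")
            coords.to_csv(fh, sep="\t", lineterminator="\n")
        written[path.name] = path

    if bundle.plspm is not None:
        coeffs = bundle.plspm.get("path_coefficients", {})
        vals = np.array([v for row in coeffs.values() for v in row.values()]
                        if isinstance(coeffs, dict) else [], dtype=float)
        if vals.size and np.any(np.isnan(vals)):
            raise ValueError("model not converged: NaN path coefficient")
        path = out / "plspm.json"
        payload = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                   **bundle.plspm}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
        written["plspm.json"] = path

    log_path = out / "run_log.txt"
    lines = [f"config_hash\t{cfg.config_hash()}", f"seed\t{cfg.seed}",
             "config\t" + json.dumps(cfg.to_dict(), sort_keys=True)]
    for key, val in bundle.extra.items():
        lines.append(f"{key}\t{json.dumps(val, sort_keys=True, default=_json_default)}")
    log_path.write_text("\n".join(lines) + "\n")
    written["run_log.txt"] = log_path
    logger.info("wrote %d artifacts to %s", len(written), out)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
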