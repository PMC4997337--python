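"""Tabular I/O, run configuration and seed plumbing.

File dialects
-------------
* OTU table: TSV, one row per taxon.  Header is ``taxon_id``, the sample
  ids, and a final ``lineage`` column holding a semicolon-delimited,
  rank-prefixed lineage (``k__...;p__...;...;f__...;g__...``).
* Factor table: a data TSV keyed by ``sample_id`` plus a dictionary TSV
  with columns ``factor, kind, timepoint, measurement_group`` declaring how
  each column is typed and which repeated-measurement construct it belongs
  to.
* Tree: Newick (see :mod:`microgrove.tree`).

Empty strings and ``NA`` are both read as missing.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InvariantError

logger = logging.getLogger("microgrove")

MISSING_MARKERS = {"", "NA", "na", "NaN", "nan"}
KINDS = ("continuous", "binary", "categorical")
TIMEPOINTS = ("pregnancy", "delivery", "NSV", "ISV")

# nominal ages (months relative to birth) used to order timepoints when a
# "closest to stool collection" decision is required
TIMEPOINT_MONTHS = {"pregnancy": -4.5, "delivery": 0.0, "NSV": 1.0, "ISV": 6.0}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed.

    Keeps every stochastic stage independently replayable: the same master
    seed and stage name always yield the same stream, and distinct stages
    get distinct streams.
    """
    s = (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
    logger.debug("stage %s -> seed %d (master %d)", stage, s, master_seed)
    return s


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def _lineage_rank(lineage: str, prefix: str) -> str:
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith(prefix):
            value = part[len(prefix):].strip()
            return value if value else "unclassified"
    return "unclassified"


@dataclass
class OtuTable:
    """Samples × taxa integer count matrix with per-taxon lineages."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_taxa), non-negative ints
    lineages: list[str]  # per taxon, semicolon-delimited with rank prefixes

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise InvariantError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(self.lineages) != len(self.taxon_ids):
            raise InvariantError("one lineage required per taxon")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise InvariantError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvariantError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise InvariantError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise InvariantError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    # -- taxonomy helpers ---------------------------------------------------
    def families(self) -> np.ndarray:
        return np.array([_lineage_rank(l, "f__") for l in self.lineages])

    def genera(self) -> np.ndarray:
        return np.array([_lineage_rank(l, "g__") for l in self.lineages])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(keep, list(self.taxon_ids), self.counts[idx], list(self.lineages))

    def select_taxa(self, keep_mask: np.ndarray) -> "OtuTable":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return OtuTable(
            list(self.sample_ids),
            [t for t, k in zip(self.taxon_ids, keep_mask) if k],
            self.counts[:, keep_mask],
            [l for l, k in zip(self.lineages, keep_mask) if k],
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_otu_table(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "taxon_id" or df.columns[-1] != "lineage":
        raise FormatError(
            "OTU table must have 'taxon_id' first and 'lineage' last; "
            f"got columns {list(df.columns[:2])}...{list(df.columns[-1:])}"
        )
    sample_ids = list(df.columns[1:-1])
    taxon_ids = df["taxon_id"].tolist()
    if len(set(taxon_ids)) != len(taxon_ids):
        dupes = df["taxon_id"][df["taxon_id"].duplicated()].tolist()
        raise FormatError(f"duplicate taxon ids: {dupes[:5]}")
    raw = df[sample_ids]
    counts = np.zeros((len(sample_ids), len(taxon_ids)), dtype=np.int64)
    for j, col in enumerate(sample_ids):
        for i, val in enumerate(raw[col]):
            try:
                x = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {val!r} at taxon {taxon_ids[i]!r}, sample {col!r}"
                ) from None
            if x < 0:
                raise FormatError(
                    f"negative count {x} at taxon {taxon_ids[i]!r}, sample {col!r}"
                )
            counts[j, i] = x
    return OtuTable(sample_ids, taxon_ids, counts, df["lineage"].tolist())


def write_otu_table(table: OtuTable, path) -> None:
    df = pd.DataFrame(table.counts.T, index=table.taxon_ids, columns=table.sample_ids)
    df.insert(0, "taxon_id", table.taxon_ids)
    df["lineage"] = table.lineages
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Factor table
# ---------------------------------------------------------------------------


@dataclass
class FactorInfo:
    kind: str  # continuous | binary | categorical
    timepoint: str  # pregnancy | delivery | NSV | ISV
    measurement_group: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise FormatError(f"unknown factor kind {self.kind!r}")
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(f"unknown timepoint {self.timepoint!r}")


@dataclass
class FactorTable:
    """Per-sample covariates plus the declared type of each factor.

    ``data`` holds continuous factors as floats (NaN = missing) and
    binary/categorical factors as pandas ``object`` columns of strings
    (NaN = missing).
    """

    data: pd.DataFrame  # index = sample ids
    info: dict[str, FactorInfo]

    def __post_init__(self):
        extra = [c for c in self.data.columns if c not in self.info]
        if extra:
            raise FormatError(f"factors missing from dictionary: {extra}")
        for name, fi in self.info.items():
            if name not in self.data.columns:
                raise FormatError(f"dictionary factor {name!r} absent from data")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def factors(self) -> list[str]:
        return list(self.data.columns)

    def kind(self, factor: str) -> str:
        return self.info[factor].kind

    def subset(self, factors: Iterable[str]) -> "FactorTable":
        factors = list(factors)
        return FactorTable(self.data[factors].copy(), {f: self.info[f] for f in factors})

    def select_samples(self, keep: Iterable[str]) -> "FactorTable":
        return FactorTable(self.data.loc[list(keep)].copy(), dict(self.info))


def _coerce_column(values: pd.Series, kind: str, name: str) -> pd.Series:
    vals = values.astype(object).where(~values.astype(str).isin(MISSING_MARKERS))
    vals = vals.where(pd.notna(vals))
    if kind == "continuous":
        out = pd.to_numeric(vals, errors="coerce")
        bad = pd.notna(vals) & out.isna()
        if bad.any():
            logger.warning(
                "factor %s: %d value(s) failed continuous parse, set missing",
                name, int(bad.sum()),
            )
        return out.astype(float)
    return vals.map(lambda v: str(v) if pd.notna(v) else np.nan)


def read_factor_table(data_path, dictionary_path) -> FactorTable:
    data = pd.read_csv(data_path, sep="\t", dtype=str)
    if data.columns[0] != "sample_id":
        raise FormatError("factor data must start with a 'sample_id' column")
    data = data.set_index("sample_id")
    ddf = pd.read_csv(dictionary_path, sep="\t", dtype=str)
    required = {"factor", "kind", "timepoint", "measurement_group"}
    if not required.issubset(ddf.columns):
        raise FormatError(f"dictionary needs columns {sorted(required)}")
    info = {
        row.factor: FactorInfo(row.kind, row.timepoint, row.measurement_group)
        for row in ddf.itertuples()
    }
    undeclared = [c for c in data.columns if c not in info]
    if undeclared:
        raise FormatError(f"data column(s) not in dictionary: {undeclared}")
    typed = pd.DataFrame(index=data.index)
    for col in data.columns:
        typed[col] = _coerce_column(data[col], info[col].kind, col)
    return FactorTable(typed, {c: info[c] for c in data.columns})


def write_factor_table(table: FactorTable, data_path, dictionary_path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(data_path, sep="\t", na_rep="NA")
    rows = [
        {"factor": f, "kind": fi.kind, "timepoint": fi.timepoint,
         "measurement_group": fi.measurement_group}
        for f, fi in table.info.items()
    ]
    pd.DataFrame(rows).to_csv(dictionary_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline-wide tunables; defaults follow the study design."""

    rarefaction_depth: int = 202367
    draws: int = 100
    permutations_single: int = 10000
    permutations_multi: int = 1000
    alpha: float = 0.05
    vif_threshold: float = 2.5
    sparsity_min_total: int = 5
    network_percentile: float = 80.0
    seed: int = 0

    def __post_init__(self):
        positives = dict(
            rarefaction_depth=self.rarefaction_depth,
            draws=self.draws,
            permutations_single=self.permutations_single,
            permutations_multi=self.permutations_multi,
            alpha=self.alpha,
            vif_threshold=self.vif_threshold,
            sparsity_min_total=self.sparsity_min_total,
        )
        for name, val in positives.items():
            if val <= 0:
                raise InvariantError(f"{name} must be positive, got {val}")
        if not 0 < self.network_percentile < 100:
            raise InvariantError("network_percentile must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
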