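"""Core data containers, file I/O, and count-table preparation.

The pipeline starts downstream of OTU picking: its primary input is a
taxa-by-samples integer read-count table with lineage annotations, paired
with a four-level sample hierarchy (biome > floodplain > zone > habitat),
a water-chemistry table, and daily discharge series.  Table preparation
follows the standard 16S workflow: drop rare taxa (prevalence and total-read
thresholds), rarefy every sample to a common depth, and optionally collapse
OTUs to a coarser lineage rank (family by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAIN_CHANNEL_HABITATS = ("riffle", "run", "pool", "confluence", "shoreline")
OFF_CHANNEL_HABITATS = (
    "backwater",
    "side-channel",
    "parafluvial-springbrook",
    "orthofluvial-springbrook",
    "pond",
)
HABITAT_ZONE = {h: "main-channel" for h in MAIN_CHANNEL_HABITATS}
HABITAT_ZONE.update({h: "off-channel" for h in OFF_CHANNEL_HABITATS})

BIOMES = ("montane", "grassland")
ZONES = ("main-channel", "off-channel")

#: Water-chemistry variables carried by :class:`EnvTable`.
ENV_VARIABLES = (
    "DOC",
    "NH4",
    "NO3",
    "DON",
    "TN",
    "SRP",
    "TP",
    "NP",
    "chla",
    "BOM",
)

GUILDS = ("heterocystous-cyanobacteria", "other-cyanobacteria", "diatom", "other")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class CountTable:
    """Taxa-by-samples read-count matrix with lineage and guild annotations.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, taxa as rows, samples as columns.
    lineage : pandas.Series, optional
        Per-taxon semicolon-delimited rank path (e.g.
        ``"Cyanobacteria;Nostocales;Nostocaceae"``), indexed like ``counts``.
    guild : pandas.Series, optional
        Per-taxon functional tag, one of :data:`GUILDS` (or ``"mixed"`` after
        a non-unanimous collapse).
    """

    counts: pd.DataFrame
    lineage: pd.Series | None = None
    guild: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("negative counts present")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("non-integer counts present")
        self.counts = c.astype(np.int64)
        for name in ("lineage", "guild"):
            s = getattr(self, name)
            if s is not None:
                s = pd.Series(s)
                missing = c.index.difference(s.index)
                if len(missing):
                    raise ValidationError(f"{name} missing for taxa: {list(missing)[:5]}")
                setattr(self, name, s.reindex(c.index))

    # -- conveniences -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised read fractions (samples each sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            raise ValidationError("sample with zero total reads")
        return self.counts / totals

    def subset_samples(self, sample_ids) -> "CountTable":
        return replace(self, counts=self.counts.loc[:, list(sample_ids)])

    def lineage_rank(self, level: int | str) -> pd.Series:
        """Label at a lineage rank; integer depth or one of phylum/order/family."""
        if self.lineage is None:
            raise ValidationError("count table has no lineage annotation")
        named = {"phylum": 0, "order": 1, "family": 2}
        depth = named.get(level, level) if isinstance(level, str) else level
        if not isinstance(depth, int):
            raise ValidationError(f"unknown lineage rank {level!r}")

        def pick(path: str) -> str | None:
            parts = [p for p in str(path).split(";") if p]
            if depth < len(parts):
                return parts[depth]
            parent = parts[-1] if parts else "root"
            return f"unclassified-{parent}"

        return self.lineage.map(pick)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        if self.lineage is not None:
            out.insert(0, "lineage", self.lineage)
        if self.guild is not None:
            out.insert(0, "guild", self.guild)
        out.to_csv(path, sep="\t", index_label="taxon_id")


@dataclass
class SampleHierarchy:
    """Per-sample membership in the biome > floodplain > zone > habitat hierarchy.

    ``table`` is indexed by sample id with columns ``biome``, ``floodplain``,
    ``zone``, ``habitat``, ``x``, ``y`` (projected coordinates, metres).
    """

    table: pd.DataFrame

    REQUIRED = ("biome", "floodplain", "zone", "habitat", "x", "y")

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        bad_biome = set(t["biome"]) - set(BIOMES)
        if bad_biome:
            raise ValidationError(f"unknown biome labels: {bad_biome}")
        bad_zone = set(t["zone"]) - set(ZONES)
        if bad_zone:
            raise ValidationError(f"unknown zone labels: {bad_zone}")
        for sid, row in t.iterrows():
            expected = HABITAT_ZONE.get(row["habitat"])
            if expected is None:
                raise ValidationError(f"{sid}: unknown habitat {row['habitat']!r}")
            if expected != row["zone"]:
                raise ValidationError(
                    f"{sid}: habitat {row['habitat']!r} inconsistent with zone "
                    f"{row['zone']!r} (expected {expected!r})"
                )
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def floodplains(self) -> list[str]:
        return sorted(self.table["floodplain"].unique())

    def subset(self, sample_ids) -> "SampleHierarchy":
        return SampleHierarchy(self.table.loc[list(sample_ids)])

    def samples_in(self, **levels) -> list[str]:
        """Sample ids matching the given level values, e.g. ``floodplain="Swan"``."""
        mask = np.ones(len(self.table), dtype=bool)
        for level, value in levels.items():
            mask &= (self.table[level] == value).to_numpy()
        return list(self.table.index[mask])

    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class EnvTable:
    """Water chemistry and benthic state per habitat sample.

    Columns: DOC, NH4, NO3, DON, TN (µg N/L or mg/L — units are carried, not
    enforced), SRP, TP, molar N:P ratio (``NP``), areal chlorophyll-a
    (``chla``) and benthic organic matter (``BOM``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        vals = t.select_dtypes(include=[np.number])
        if (vals.to_numpy() < 0).any():
            raise ValidationError("environmental values must be non-negative")
        if "NP" in t.columns and "TP" in t.columns:
            pos = t["TP"] > 0
            if not np.isfinite(t.loc[pos, "NP"].to_numpy(dtype=float)).all():
                raise ValidationError("non-finite N:P where TP > 0")
        self.table = t

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def log_standardized(self, variables=None, offset: float = 1e-9) -> pd.DataFrame:
        """log-transform then z-score each variable (the pre-ordination convention)."""
        cols = list(variables) if variables is not None else self.variables
        x = np.log(self.table[cols].astype(float) + offset)
        return (x - x.mean()) / x.std(ddof=1)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class FlowSeries:
    """Daily discharge series for one river."""

    river: str
    dates: pd.DatetimeIndex
    discharge: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        q = np.asarray(self.discharge, dtype=float)
        if len(q) != len(self.dates):
            raise ValidationError("dates and discharge lengths differ")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValidationError("dates must be strictly increasing")
        if np.any(q < 0):
            raise ValidationError("negative discharge")
        self.discharge = q

    def __len__(self) -> int:
        return len(self.discharge)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "discharge": self.discharge})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, river: str | None = None) -> "FlowSeries":
        df = pd.read_csv(path, sep="\t")
        if not {"date", "discharge"} <= set(df.columns):
            raise ValidationError(f"{path}: need columns date, discharge")
        name = river if river is not None else str(path)
        return cls(name, pd.DatetimeIndex(pd.to_datetime(df["date"])), df["discharge"].to_numpy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv", taxa_as_rows: bool = True) -> CountTable:
    """Read a count table from TSV or BIOM-style JSON.

    The TSV layout is taxa as rows, a ``taxon_id`` index column, optional
    ``lineage`` and ``guild`` annotation columns, remaining columns one per
    sample.  Set ``taxa_as_rows=False`` if the file is oriented samples-by-taxa.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"{path}: parse error: {exc}") from exc
        lineage = df.pop("lineage") if "lineage" in df.columns else None
        guild = df.pop("guild") if "guild" in df.columns else None
        if not taxa_as_rows:
            df = df.T
        df.index.name = None
        df.columns.name = None
        return CountTable(df, lineage=lineage, guild=guild)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        lineage = pd.Series(
            {
                r["id"]: ";".join(r.get("metadata", {}).get("taxonomy", []))
                for r in doc["rows"]
                if r.get("metadata")
            }
        )
        lineage = lineage.reindex(taxa) if len(lineage) else None
        return CountTable(pd.DataFrame(mat, index=taxa, columns=samples), lineage=lineage)
    raise ValidationError(f"unknown count-table format {format!r}")


def read_metadata(path) -> SampleHierarchy:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleHierarchy(df)


def read_env_table(path) -> EnvTable:
    return EnvTable(pd.read_csv(path, sep="\t", index_col="sample_id"))


# ---------------------------------------------------------------------------
# Table preparation
# ---------------------------------------------------------------------------

def filter_taxa(
    t: CountTable,
    min_prevalence_fraction: float = 0.25,
    min_total_reads: int = 20,
    require_both: bool = True,
) -> CountTable:
    """Drop rare taxa: those below the prevalence or total-read thresholds.

    With ``require_both`` (default) a taxon is retained only if it occurs in at
    least ``min_prevalence_fraction`` of samples AND carries at least
    ``min_total_reads`` reads overall — i.e. removal if either rule fails, the
    stricter reading of an and/or rule.  Set ``require_both=False`` to retain
    taxa passing either threshold.
    """
    c = t.counts
    n_samples = c.shape[1]
    prevalence = (c > 0).sum(axis=1) / n_samples
    totals = c.sum(axis=1)
    prev_ok = prevalence >= min_prevalence_fraction
    reads_ok = totals >= min_total_reads
    keep = (prev_ok & reads_ok) if require_both else (prev_ok | reads_ok)
    if not keep.any():
        warnings.warn("filter_taxa removed every taxon", stacklevel=2)
    return CountTable(
        c.loc[keep],
        lineage=t.lineage[keep] if t.lineage is not None else None,
        guild=t.guild[keep] if t.guild is not None else None,
    )


def rarefy(t: CountTable, depth: int = 10_000, seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a warning
    naming them); a single seeded draw is taken, not an average over draws.
    """
    rng = np.random.default_rng(seed)
    c = t.counts
    totals = c.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    dropped = list(c.columns[~keep])
    if dropped:
        warnings.warn(f"rarefy dropped {len(dropped)} sample(s) below depth {depth}: {dropped}", stacklevel=2)
    out = {}
    for sid in c.columns[keep]:
        col = c[sid].to_numpy()
        total = col.sum()
        if total == depth:
            out[sid] = col
            continue
        # multivariate hypergeometric draw = without-replacement subsampling
        out[sid] = rng.multivariate_hypergeometric(col, depth)
    new = pd.DataFrame(out, index=c.index)
    return CountTable(new, lineage=t.lineage, guild=t.guild)


def collapse_taxa(t: CountTable, level: int | str = "family") -> CountTable:
    """Sum counts over taxa sharing a lineage rank (family by default).

    The guild tag propagates when unanimous among members, otherwise becomes
    ``"mixed"``; taxa lacking the rank pool into ``unclassified-<parent>``.
    """
    labels = t.lineage_rank(level)
    grouped = t.counts.groupby(labels, sort=True).sum()
    lineage = pd.Series(grouped.index, index=grouped.index)
    guild = None
    if t.guild is not None:
        def agg(g: pd.Series) -> str:
            u = g.dropna().unique()
            return u[0] if len(u) == 1 else "mixed"

        guild = t.guild.groupby(labels).agg(agg).reindex(grouped.index)
    return CountTable(grouped, lineage=lineage, guild=guild)
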