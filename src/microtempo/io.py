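"""Reading, validation and writing of the pipeline's table formats.

Five input formats are supported: ASV count tables (taxa x samples, TSV),
sample metadata (TSV), taxonomy tables (TSV), daily climate tables (CSV)
and fungal guild lookup tables (TSV).  All result tables are written as
tab-separated text with a header row and full numeric precision, so every
write/read round-trip is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HABITATS = ("leaf_endosphere", "root_endosphere", "rhizosphere")
DOMAINS = ("bacteria_archaea", "fungi")
SEASONS = ("winter", "spring", "summer", "fall")
SPECIES = ("P_trichocarpa", "P_deltoides")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

CLIMATE_VARIABLES = ("tmin", "tmax", "day_length", "srad", "precip", "vapor_pressure")

METADATA_COLUMNS = (
    "habitat",
    "domain",
    "season",
    "year",
    "date",
    "genotype",
    "species",
    "block",
)


class ValidationError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class CountTable:
    """Nonnegative integer ASV x sample count matrix for one community.

    ``counts`` is indexed by ASV identifier with one column per sample.
    ``habitat`` and ``domain`` tag which of the six study communities the
    table belongs to (they may be ``None`` for generic tables).
    """

    counts: pd.DataFrame
    habitat: str | None = None
    domain: str | None = None

    def __post_init__(self) -> None:
        validate_counts(self.counts)
        if self.habitat is not None and self.habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {self.habitat!r}")
        if self.domain is not None and self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)], self.habitat, self.domain)


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the CountTable invariants, naming the offending cell on failure."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValidationError(f"duplicate ASV identifier {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample identifier {dup!r}")
    values = counts.to_numpy()
    if values.size == 0:
        raise ValidationError("empty count table")
    bad = ~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"count at ASV {counts.index[i]!r}, sample {counts.columns[j]!r} "
            f"is {values[i, j]!r}: counts must be nonnegative integers"
        )
    colsums = values.sum(axis=0)
    if (colsums <= 0).any():
        j = int(np.argmax(colsums <= 0))
        raise ValidationError(f"sample {counts.columns[j]!r} has zero total count")


def validate_metadata(metadata: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    if metadata.index.duplicated().any():
        dup = metadata.index[metadata.index.duplicated()][0]
        raise ValidationError(f"duplicate sample identifier {dup!r} in metadata")
    for col, allowed in (
        ("habitat", HABITATS),
        ("domain", DOMAINS),
        ("season", SEASONS),
        ("species", SPECIES),
    ):
        bad = set(metadata[col].unique()) - set(allowed)
        if bad:
            raise ValidationError(f"metadata column {col!r} has unknown level(s) {bad}")
    leaf_winter = (metadata["habitat"] == "leaf_endosphere") & (
        metadata["season"] == "winter"
    )
    if leaf_winter.any():
        raise ValidationError(
            f"leaf endosphere sample {metadata.index[leaf_winter.to_numpy()][0]!r} "
            "recorded in winter (deciduous hosts carry no winter leaves)"
        )
    # genotype must determine species
    per_geno = metadata.groupby("genotype")["species"].nunique()
    if (per_geno > 1).any():
        geno = per_geno.index[per_geno.to_numpy() > 1][0]
        raise ValidationError(f"genotype {geno!r} maps to more than one species")


def load_dataset(
    counts_path,
    metadata_path,
    taxonomy_path,
    habitat: str | None = None,
    domain: str | None = None,
    transpose: bool = False,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a count table, its metadata and taxonomy.

    Counts are expected ASVs-as-rows / samples-as-columns; ``transpose=True``
    flips the orientation on read.  Every sample in the counts must have a
    metadata row (fatal otherwise); ASVs without a taxonomy row are filled
    with an "unclassified" lineage.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if transpose:
        counts = counts.T
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    validate_counts(counts)

    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    metadata["date"] = pd.to_datetime(metadata["date"])
    validate_metadata(metadata)

    absent = [s for s in counts.columns if s not in metadata.index]
    if absent:
        raise ValidationError(
            f"sample(s) {absent} present in counts but absent from metadata"
        )

    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    taxonomy.index = taxonomy.index.astype(str)
    if taxonomy.index.duplicated().any():
        dup = taxonomy.index[taxonomy.index.duplicated()][0]
        raise ValidationError(f"duplicate ASV identifier {dup!r} in taxonomy")
    missing_tax = [a for a in counts.index if a not in taxonomy.index]
    if missing_tax:
        filler = pd.DataFrame(
            "unclassified", index=missing_tax, columns=taxonomy.columns
        )
        taxonomy = pd.concat([taxonomy, filler])
    taxonomy = taxonomy.loc[counts.index]
    validate_taxonomy(taxonomy)

    table = CountTable(counts, habitat=habitat, domain=domain)
    return table, metadata.loc[counts.columns], taxonomy


def validate_taxonomy(taxonomy: pd.DataFrame) -> None:
    """Ranks must form a prefix: no assigned rank below a missing one."""
    ranks = [c for c in TAXONOMY_RANKS if c in taxonomy.columns]
    values = taxonomy[ranks].astype(object)
    filled = values.notna() & (values != "") & (values != "unclassified")
    arr = filled.to_numpy()
    for i in range(arr.shape[0]):
        row = arr[i]
        if row.any():
            last = int(np.max(np.nonzero(row)))
            if not row[: last + 1].all():
                raise ValidationError(
                    f"taxonomy for {taxonomy.index[i]!r} has a gap below a "
                    "missing rank"
                )


def load_climate(path) -> pd.DataFrame:
    """Read a daily climate CSV (date + six variables), sorted by date."""
    climate = pd.read_csv(path)
    missing = [c for c in CLIMATE_VARIABLES if c not in climate.columns]
    if missing:
        raise ValidationError(f"climate table missing variable column(s): {missing}")
    if "date" not in climate.columns:
        raise ValidationError("climate table missing 'date' column")
    try:
        climate["date"] = pd.to_datetime(climate["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable climate date: {exc}") from exc
    if climate["date"].duplicated().any():
        dup = climate.loc[climate["date"].duplicated(), "date"].iloc[0]
        raise ValidationError(f"duplicate climate date {dup.date()}")
    climate = climate.sort_values("date").reset_index(drop=True)
    bad = climate["tmin"] > climate["tmax"]
    if bad.any():
        raise ValidationError(
            f"tmin > tmax on {climate.loc[bad, 'date'].iloc[0].date()}"
        )
    for col in ("day_length", "srad", "precip", "vapor_pressure"):
        if (climate[col] < 0).any():
            raise ValidationError(f"negative value in climate column {col!r}")
    return climate


def write_table(result: pd.DataFrame, path, index: bool = True) -> None:
    """Write any result table as TSV at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col=index_col, float_precision="round_trip"
    )


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    if not d.index.equals(d.columns):
        raise ValidationError("distance matrix must have identical row/column ids")
    write_table(d, path)


def read_distance_matrix(path) -> pd.DataFrame:
    d = read_table(path)
    d.index = d.index.astype(str)
    d.columns = d.columns.astype(str)
    validate_distance_matrix(d)
    return d


def validate_distance_matrix(d: pd.DataFrame, atol: float = 1e-8) -> None:
    values = d.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError("distance matrix is not square")
    if not np.allclose(values, values.T, atol=atol):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=atol):
        raise ValidationError("distance matrix diagonal is not zero")
    if (values < -atol).any():
        raise ValidationError("distance matrix has negative entries")


def write_count_table(table: CountTable, path) -> None:
    write_table(table.counts, path)


def read_count_table(path, habitat=None, domain=None) -> CountTable:
    counts = read_table(path)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountTable(counts, habitat=habitat, domain=domain)
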