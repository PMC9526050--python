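"""Genome model and tabular I/O for local-ancestry tracts, ROH/IBD segments and samples.

All coordinates are 0-based, half-open (BED convention).  Genetic lengths are
derived from a constant per-chromosome recombination rate in cM/Mb (default
1 cM/Mb, the commonly applied baseline); per-interval genetic maps are a
declared extension point but not implemented.

Ancestry labels are fixed to ``S1`` and ``S2``; all ancestry statistics in the
package are reported for S1.  The male X is modelled as a single haplotype
(index 0); pseudoautosomal regions are ignored.

File formats (UTF-8, LF, tab-delimited, one header line):

* tract file:   ``sample hap chrom start end ancestry``
* segment file: ``kind sample1 hap1 sample2 hap2 chrom start end cM class``
* sample file:  ``sample sex population generation mother father``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ANCESTRIES = ("S1", "S2")

TRACT_COLUMNS = ["sample", "hap", "chrom", "start", "end", "ancestry"]
SEGMENT_COLUMNS = [
    "kind", "sample1", "hap1", "sample2", "hap2",
    "chrom", "start", "end", "cM", "class",
]
SAMPLE_COLUMNS = ["sample", "sex", "population", "generation", "mother", "father"]


class GenomeFormatError(ValueError):
    """Malformed or inconsistent tract/segment/sample table."""


class TilingError(GenomeFormatError):
    """Tracts fail to tile a haplotype exactly (overlap or gap)."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome with a constant recombination rate.

    Parameters
    ----------
    name : str
        Unique chromosome name (e.g. ``"chr1"``, ``"chrX"``).
    length_bp : int
        Physical length in base pairs; must be positive.
    rate_cm_per_mb : float
        Constant recombination rate, cM per Mb.
    is_x : bool
        Whether this is the X chromosome (hemizygous in males).
    """

    name: str
    length_bp: int
    rate_cm_per_mb: float = 1.0
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be positive")
        if self.rate_cm_per_mb <= 0:
            raise ValueError(f"chromosome {self.name}: rate must be positive")

    @property
    def length_cm(self) -> float:
        return self.length_bp * self.rate_cm_per_mb / 1e6

    @property
    def length_morgans(self) -> float:
        return self.length_cm / 100.0

    def bp_to_cm(self, start_bp, end_bp):
        """Genetic length of [start_bp, end_bp) under the constant rate."""
        return (np.asarray(end_bp) - np.asarray(start_bp)) * self.rate_cm_per_mb / 1e6


@dataclass(frozen=True)
class GeneticMap:
    """Ordered collection of chromosomes with at most one X."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if sum(c.is_x for c in self.chromosomes) > 1:
            raise ValueError("at most one X chromosome allowed")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    @classmethod
    def uniform(
        cls,
        lengths_mb: Sequence[float],
        rate_cm_per_mb: float = 1.0,
        x_mb: float | None = None,
    ) -> "GeneticMap":
        """Build a map of autosomes ``chr1..chrN`` plus an optional ``chrX``."""
        chroms = [
            Chromosome(f"chr{i + 1}", int(round(mb * 1e6)), rate_cm_per_mb)
            for i, mb in enumerate(lengths_mb)
        ]
        if x_mb is not None:
            chroms.append(Chromosome("chrX", int(round(x_mb * 1e6)), rate_cm_per_mb, is_x=True))
        return cls(tuple(chroms))

    def __iter__(self):
        return iter(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def chrom(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise GenomeFormatError(f"unknown chromosome {name!r}") from None

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_x)

    @property
    def x(self) -> Chromosome | None:
        for c in self.chromosomes:
            if c.is_x:
                return c
        return None

    def total_cm(self, scope: str = "autosomes") -> float:
        """Total genetic length of a scope: ``autosomes``, ``X`` or ``all``."""
        if scope == "autosomes":
            chroms = self.autosomes
        elif scope in ("X", "x"):
            chroms = (self.x,) if self.x is not None else ()
        elif scope == "all":
            chroms = self.chromosomes
        else:
            raise ValueError(f"unknown scope {scope!r}")
        return float(sum(c.length_cm for c in chroms))


def _as_tract_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df[TRACT_COLUMNS].copy()
    df["hap"] = df["hap"].astype(np.int8)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def _sorted_tracts(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["sample", "hap", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class AncestryTractSet:
    """Per-sample, per-haplotype tiling of two-source local ancestry.

    ``df`` holds rows (sample, hap, chrom, start, end, ancestry), 0-based
    half-open, with ancestry in {"S1", "S2"}.  Per (sample, hap, chrom) the
    tracts must be non-overlapping, sorted, and tile [0, length_bp) exactly.
    """

    df: pd.DataFrame
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.df = _sorted_tracts(_as_tract_frame(self.df))
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df.empty:
            return
        bad = set(df["ancestry"].unique()) - set(ANCESTRIES)
        if bad:
            raise GenomeFormatError(f"unknown ancestry labels: {sorted(bad)}")
        bad_haps = set(df["hap"].unique()) - {0, 1}
        if bad_haps:
            raise GenomeFormatError(f"haplotype index must be 0 or 1, got {sorted(bad_haps)}")
        for name in df["chrom"].unique():
            self.gmap.chrom(name)  # raises on unknown chromosome
        lengths = df["chrom"].map({c.name: c.length_bp for c in self.gmap})
        # vectorised tiling check on the sorted frame
        key = (
            df["sample"].astype(str) + "\x00"
            + df["hap"].astype(str) + "\x00" + df["chrom"].astype(str)
        ).to_numpy()
        new_group = np.empty(len(df), dtype=bool)
        new_group[0] = True
        new_group[1:] = key[1:] != key[:-1]
        last_in_group = np.roll(new_group, -1)
        start = df["start"].to_numpy()
        end = df["end"].to_numpy()
        if np.any(end <= start):
            i = int(np.argmax(end <= start))
            raise GenomeFormatError(
                f"empty or negative tract at {df['sample'].iat[i]} hap "
                f"{df['hap'].iat[i]} {df['chrom'].iat[i]}:{start[i]}-{end[i]}"
            )
        first_bad = new_group & (start != 0)
        contig_bad = np.zeros(len(df), dtype=bool)
        contig_bad[1:] = (~new_group[1:]) & (start[1:] != end[:-1])
        last_bad = last_in_group & (end != lengths.to_numpy())
        for mask, what in ((first_bad, "does not start at 0"),
                           (contig_bad, "gap or overlap"),
                           (last_bad, "does not reach chromosome end")):
            if mask.any():
                i = int(np.argmax(mask))
                raise TilingError(
                    f"tiling violation ({what}) at sample {df['sample'].iat[i]} "
                    f"hap {df['hap'].iat[i]} {df['chrom'].iat[i]} position {start[i]}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AncestryTractSet):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def with_cm(self) -> pd.DataFrame:
        """Tract frame plus a ``cM`` column of genetic lengths."""
        df = self.df.copy()
        rate = df["chrom"].map({c.name: c.rate_cm_per_mb for c in self.gmap})
        df["cM"] = (df["end"] - df["start"]) * rate / 1e6
        return df


@dataclass
class SampleTable:
    """Sample metadata: sex (F/M), population, optional generation and parents."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df[SAMPLE_COLUMNS].copy()
        df["sample"] = df["sample"].astype(str)
        self.df = df.sort_values("sample", kind="mergesort").reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise GenomeFormatError(f"duplicate sample id {dup!r}")
        bad = set(df["sex"].unique()) - {"F", "M"}
        if bad:
            raise GenomeFormatError(f"sex must be F or M, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample"], self.df["sex"]))

    @property
    def female_fraction(self) -> float:
        return float((self.df["sex"] == "F").mean())


def _as_segment_frame(df: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    df = df[SEGMENT_COLUMNS].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        i = int(np.argmax((df["end"] <= df["start"]).to_numpy()))
        raise GenomeFormatError(
            f"segment with non-positive length at row {i}: "
            f"{df['chrom'].iat[i]}:{df['start'].iat[i]}-{df['end'].iat[i]}"
        )
    bad_kind = set(df["kind"].unique()) - {"ROH", "IBD"}
    if bad_kind:
        raise GenomeFormatError(f"segment kind must be ROH or IBD, got {sorted(bad_kind)}")
    ibd = df["kind"] == "IBD"
    missing = ibd & (df["sample2"].isna() | (df["sample2"].astype(str) == ""))
    if missing.any():
        i = int(np.argmax(missing.to_numpy()))
        raise GenomeFormatError(f"IBD row {i} is missing its partner sample")
    roh = ~ibd
    df.loc[roh, "sample2"] = ""
    df.loc[roh, "hap2"] = np.nan
    rate = df["chrom"].map({c.name: c.rate_cm_per_mb for c in gmap})
    if rate.isna().any():
        name = df.loc[rate.isna(), "chrom"].iloc[0]
        raise GenomeFormatError(f"unknown chromosome {name!r}")
    need = df["cM"].isna()
    if need.any():
        df.loc[need, "cM"] = (df.loc[need, "end"] - df.loc[need, "start"]) * rate[need] / 1e6
    return df


@dataclass
class SegmentTable:
    """ROH or IBD intervals with genetic lengths and optional class labels.

    ROH rows have blank partner fields (``sample2``/``hap2``); IBD rows name
    both haplotypes.  ``cM`` is recomputed from the map when absent.
    """

    df: pd.DataFrame
    gmap: GeneticMap

    def __post_init__(self) -> None:
        df = _as_segment_frame(self.df, self.gmap)
        self.df = df.sort_values(
            ["kind", "sample1", "sample2", "chrom", "start", "hap1", "hap2"],
            kind="mergesort",
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentTable):
            return NotImplemented
        return self.df.equals(other.df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind]


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise GenomeFormatError(
            f"{path}: expected header {columns}, found {list(df.columns)}"
        )
    return df


def read_tracts(path, gmap: GeneticMap) -> AncestryTractSet:
    """Read and validate a tract file (tiling invariant enforced)."""
    df = _read_table(path, TRACT_COLUMNS)
    if not df.empty:
        df["hap"] = df["hap"].astype(int)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    else:
        df = df.astype({"hap": int, "start": np.int64, "end": np.int64})
    return AncestryTractSet(df, gmap)


def write_tracts(tracts: AncestryTractSet, path) -> None:
    """Write a tract file with deterministic (sample, hap, chrom, start) order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tracts.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_samples(path) -> SampleTable:
    df = _read_table(path, SAMPLE_COLUMNS)
    return SampleTable(df)


def write_samples(samples: SampleTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = samples.df.copy()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def read_segments(path, gmap: GeneticMap) -> SegmentTable:
    """Read ROH/IBD segments; ``cM`` is recomputed from the map when blank."""
    df = _read_table(path, SEGMENT_COLUMNS)
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "cM": float, "hap1": float, "hap2": float})
        return SegmentTable(df, gmap)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    for col in ("hap1", "hap2", "cM"):
        df[col] = pd.to_numeric(df[col].where(df[col] != "", np.nan))
    return SegmentTable(df, gmap)


def write_segments(table: SegmentTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = table.df.copy()
    for col in ("hap1", "hap2"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")
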