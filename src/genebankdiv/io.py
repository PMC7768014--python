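"""Reading, validation and quality filtering of genotype and phenotype data.

Genotypes are biallelic SNP calls for individual plants grouped into
accessions, coded by alternate-allele dosage (0 = hom ref, 1 = het,
2 = hom alt, ``MISSING`` = no call).  Two on-disk representations are
supported: VCF (v4.x, GT field, biallelic records) and a "DArT-style"
single-row counts CSV with one row per locus, locus metadata columns and
one 0/1/2 column per individual.

Quality filtering follows common genotyping-by-sequencing practice for
genebank material: markers are kept by reproducibility and call rate,
samples by overall missingness, and no minor-allele-frequency filter is
ever applied so that rare allele variants are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never 0: a missing call is not a
#: reference-homozygote call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


class GenotypeDataError(ValueError):
    """Raised for malformed or inconsistent genotype/phenotype inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix with accession grouping.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    individual_ids
        Unique identifiers, one per row.
    accessions
        Accession label per individual (non-empty strings).
    loci
        Per-locus metadata frame indexed by unique ``locus_id`` with columns
        ``chromosome`` (str), ``position`` (1-based bp, may be NaN),
        and optionally ``reproducibility`` and ``call_rate`` in [0, 1].
    """

    genotypes: np.ndarray
    individual_ids: np.ndarray
    accessions: np.ndarray
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.accessions = np.asarray(self.accessions, dtype=object)
        if self.genotypes.ndim != 2:
            raise GenotypeDataError("genotypes must be 2-D")
        n, m = self.genotypes.shape
        if len(self.individual_ids) != n or len(self.accessions) != n:
            raise GenotypeDataError("individual ids / accession labels do not match row count")
        if len(self.loci) != m:
            raise GenotypeDataError("locus metadata does not match column count")
        if len(set(self.individual_ids)) != n:
            raise GenotypeDataError("duplicate individual ids")
        if self.loci.index.has_duplicates:
            raise GenotypeDataError("duplicate locus ids")
        if any(a is None or str(a) == "" for a in self.accessions):
            raise GenotypeDataError("every individual needs a non-empty accession label")
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise GenotypeDataError(f"invalid genotype codes: {sorted(bad)}")
        if "position" in self.loci.columns:
            pos = self.loci["position"].dropna()
            if (pos < 1).any():
                raise GenotypeDataError("positions must be >= 1 (1-based)")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def accession_names(self) -> list[str]:
        """Accession labels in first-appearance order."""
        return list(pd.unique(self.accessions))

    def individuals_of(self, accession: str) -> np.ndarray:
        idx = np.flatnonzero(self.accessions == accession)
        if idx.size == 0:
            raise KeyError(f"no such accession: {accession!r}")
        return idx

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    # -- subsetting --------------------------------------------------------
    def select_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            self.genotypes[:, idx], self.individual_ids, self.accessions,
            self.loci.iloc[idx] if idx.dtype != bool else self.loci.loc[idx],
        )

    def select_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            self.genotypes[idx], self.individual_ids[idx], self.accessions[idx], self.loci,
        )


@dataclass
class PhenotypeTable:
    """Individuals x mixed quantitative/qualitative traits with accessions.

    ``data`` is indexed by individual id; ``kinds`` declares every trait
    column as quantitative (numeric, missing allowed) or qualitative
    (categorical labels, missing allowed).
    """

    data: pd.DataFrame
    accessions: np.ndarray
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        self.accessions = np.asarray(self.accessions, dtype=object)
        if len(self.accessions) != len(self.data):
            raise GenotypeDataError("accession labels do not match row count")
        if not self.kinds:
            raise GenotypeDataError("at least one trait is required")
        undeclared = [c for c in self.data.columns if c not in self.kinds]
        if undeclared:
            raise GenotypeDataError(f"traits without a declared kind: {undeclared}")
        missing_cols = [t for t in self.kinds if t not in self.data.columns]
        if missing_cols:
            raise GenotypeDataError(f"declared traits absent from table: {missing_cols}")
        for name, kind in self.kinds.items():
            if kind not in (QUANTITATIVE, QUALITATIVE):
                raise GenotypeDataError(f"unknown trait kind {kind!r} for {name!r}")
            if kind == QUANTITATIVE and not pd.api.types.is_numeric_dtype(self.data[name]):
                raise GenotypeDataError(f"quantitative trait {name!r} is not numeric")

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def individual_ids(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=object)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass (loci or individuals)."""

    n_loci_in: int
    n_loci_out: int
    n_individuals_in: int
    n_individuals_out: int
    thresholds: dict[str, float]
    dropped_by: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_loci_out > self.n_loci_in or self.n_individuals_out > self.n_individuals_in:
            raise GenotypeDataError("filter cannot add loci or individuals")
        n_dropped = sum(self.dropped_by.values())
        lost = (self.n_loci_in - self.n_loci_out) + (self.n_individuals_in - self.n_individuals_out)
        if n_dropped != lost:
            raise GenotypeDataError("per-criterion drop counts inconsistent with totals")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_accession_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise GenotypeDataError("accession map needs columns individual_id, accession_id")
    ids, accs = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise GenotypeDataError("duplicate individual ids in accession map")
    return dict(zip(ids, accs))


def read_genotypes(
    path: str | Path,
    format: Literal["vcf", "dart_csv"],
    accession_map: str | Path | Mapping[str, str] | None = None,
    multiallelic: Literal["error", "drop"] = "error",
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a DArT-style counts CSV.

    ``accession_map`` maps each sample/individual id to its accession label;
    a path is read as a two-column CSV (individual_id, accession_id).
    Multi-allelic VCF records are rejected (``error``) or dropped per
    ``multiallelic``.
    """
    if isinstance(accession_map, (str, Path)):
        accession_map = _read_accession_map(accession_map)
    if format == "vcf":
        gm = _read_vcf(path, multiallelic)
    elif format == "dart_csv":
        gm = _read_dart_csv(path)
    else:
        raise GenotypeDataError(f"unknown format {format!r}")
    if accession_map is None:
        raise GenotypeDataError("an accession map is required")
    missing = [i for i in gm.individual_ids if i not in accession_map]
    if missing:
        raise GenotypeDataError(f"individuals absent from accession map: {missing[:5]}")
    accs = np.array([accession_map[i] for i in gm.individual_ids], dtype=object)
    return GenotypeMatrix(gm.genotypes, gm.individual_ids, accs, gm.loci)


def _read_vcf(path: str | Path, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            rec = f"{var.CHROM}:{var.POS} ({var.ID or '.'})"
            if multiallelic == "error":
                raise GenotypeDataError(f"multi-allelic record not supported: {rec}")
            logger.warning("dropping multi-allelic record %s", rec)
            continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                codes[j] = sum(1 for a in alleles if a > 0)
        rows.append(codes)
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        meta.append({"locus_id": locus_id, "chromosome": var.CHROM, "position": var.POS})
    if not rows:
        raise GenotypeDataError(f"no usable biallelic records in {path}")
    loci = pd.DataFrame(meta).set_index("locus_id")
    if loci.index.has_duplicates:
        raise GenotypeDataError("duplicate locus ids in VCF")
    gt = np.stack(rows, axis=1)
    ids = np.array(samples, dtype=object)
    return GenotypeMatrix(gt, ids, np.array(["_pending_"] * len(ids), dtype=object), loci)


_DART_META_COLS = {"locus_id", "chromosome", "position", "reproducibility", "call_rate"}


def _read_dart_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    if "locus_id" not in df.columns:
        raise GenotypeDataError("dart_csv requires a locus_id column")
    meta_cols = [c for c in df.columns if c in _DART_META_COLS]
    sample_cols = [c for c in df.columns if c not in _DART_META_COLS]
    if not sample_cols:
        raise GenotypeDataError("dart_csv has no individual columns")
    loci = df[meta_cols].set_index("locus_id")
    for col, caster in (("position", "Int64"), ("reproducibility", float), ("call_rate", float)):
        if col in loci.columns:
            loci[col] = pd.to_numeric(loci[col], errors="raise")
    codes = np.full((len(sample_cols), len(df)), MISSING, dtype=np.int8)
    for j, col in enumerate(sample_cols):
        vals = df[col].fillna("-").astype(str).str.strip()
        ok = vals.isin(["0", "1", "2"])
        bad = ~ok & ~vals.isin(["-", "", "NA", "nan"])
        if bad.any():
            raise GenotypeDataError(
                f"malformed genotype cells in column {col!r}: {sorted(vals[bad].unique())[:5]}"
            )
        codes[j, ok.to_numpy()] = vals[ok].astype(np.int8)
    ids = np.array(sample_cols, dtype=object)
    return GenotypeMatrix(codes, ids, np.array(["_pending_"] * len(ids), dtype=object), loci)


def read_phenotypes(path: str | Path, trait_spec: Mapping[str, str]) -> PhenotypeTable:
    """Read a phenotype CSV (individual_id, accession, then trait columns).

    ``trait_spec`` declares every trait column's kind.  Unparseable cells in
    quantitative columns become missing, with the count logged.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise GenotypeDataError("empty phenotype table")
    required = {"individual_id", "accession"}
    if not required <= set(df.columns):
        raise GenotypeDataError(f"phenotype CSV needs columns {sorted(required)}")
    trait_cols = [c for c in df.columns if c not in required]
    undeclared = [c for c in trait_cols if c not in trait_spec]
    if undeclared:
        raise GenotypeDataError(f"undeclared trait columns: {undeclared}")
    data = df[trait_cols].copy()
    for name in trait_cols:
        if trait_spec[name] == QUANTITATIVE:
            raw_missing = data[name].isna() | data[name].str.strip().isin(["", "NA"])
            parsed = pd.to_numeric(data[name], errors="coerce")
            n_bad = int((parsed.isna() & ~raw_missing).sum())
            if n_bad:
                logger.warning("trait %r: %d unparseable numeric cells set to missing", name, n_bad)
            data[name] = parsed
    data.index = pd.Index(df["individual_id"], name="individual_id")
    kinds = {name: trait_spec[name] for name in trait_cols}
    return PhenotypeTable(data, df["accession"].to_numpy(dtype=object), kinds)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_markers(
    g: GenotypeMatrix,
    min_reproducibility: float = 0.95,
    min_call_rate: float = 0.80,
    strict_reproducibility: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci with reproducibility >= threshold and call rate >= threshold.

    The call rate is the observed fraction of non-missing calls.  Loci
    lacking a reproducibility field pass that criterion by default; with
    ``strict_reproducibility`` they are dropped.  There is deliberately no
    minor-allele-frequency filter anywhere in this package: rare variants
    are the object of study, not noise.
    """
    for t in (min_reproducibility, min_call_rate):
        if not 0.0 <= t <= 1.0:
            raise GenotypeDataError("thresholds must lie in [0, 1]")
    n_in = g.n_loci
    keep = np.ones(n_in, dtype=bool)
    dropped: dict[str, int] = {}

    if "reproducibility" in g.loci.columns:
        rep = pd.to_numeric(g.loci["reproducibility"], errors="coerce").to_numpy(float)
    else:
        rep = np.full(n_in, np.nan)
    has_rep = ~np.isnan(rep)
    ok_rep = np.where(has_rep, rep >= min_reproducibility, not strict_reproducibility)
    dropped["reproducibility"] = int((~ok_rep & keep).sum())
    keep &= ok_rep

    called = (~g.missing_mask).mean(axis=0)
    ok_cr = called >= min_call_rate
    dropped["call_rate"] = int((~ok_cr & keep).sum())
    keep &= ok_cr

    if not keep.any():
        raise GenotypeDataError(
            "all loci removed by marker filters; review the thresholds"
        )
    out = g.select_loci(np.flatnonzero(keep))
    report = FilterReport(
        n_loci_in=n_in, n_loci_out=out.n_loci,
        n_individuals_in=g.n_individuals, n_individuals_out=g.n_individuals,
        thresholds={"min_reproducibility": min_reproducibility, "min_call_rate": min_call_rate},
        dropped_by=dropped,
    )
    return out, report


def filter_samples(
    g: GenotypeMatrix, max_missing: float = 0.50
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals whose missing-call fraction exceeds ``max_missing``.

    Strict ``>`` comparison: an individual at exactly the threshold is kept.
    Accessions emptied or shrunk by the filter are listed in the report.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise GenotypeDataError("max_missing must lie in [0, 1]")
    frac = g.missing_mask.mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise GenotypeDataError("all individuals removed by the missingness filter")
    out = g.select_individuals(np.flatnonzero(keep))
    notes = []
    before = pd.Series(g.accessions).value_counts()
    after = pd.Series(out.accessions).value_counts()
    for acc, n_before in before.items():
        n_after = int(after.get(acc, 0))
        if n_after == 0:
            notes.append(f"accession {acc!r} lost all individuals")
        elif n_after < n_before:
            notes.append(f"accession {acc!r} reduced from {n_before} to {n_after} individuals")
    report = FilterReport(
        n_loci_in=g.n_loci, n_loci_out=g.n_loci,
        n_individuals_in=g.n_individuals, n_individuals_out=out.n_individuals,
        thresholds={"max_missing": max_missing},
        dropped_by={"sample_missingness": int((~keep).sum())},
        notes=notes,
    )
    return out, report


# ---------------------------------------------------------------------------
# Frequencies and densities
# ---------------------------------------------------------------------------

def allele_frequencies(
    g: GenotypeMatrix, scope: Literal["overall", "per_accession"] = "overall"
) -> pd.DataFrame:
    """Alternate-allele frequencies per locus.

    Frequency = alt allele count / (2 x non-missing individuals) in the
    scope.  Loci with no calls in a scope get NaN (undefined), never a
    silent 0.  ``overall`` returns one column ``overall``; ``per_accession``
    one column per accession.
    """
    if g.n_individuals == 0:
        raise GenotypeDataError("empty genotype matrix")

    def freq(rows: np.ndarray) -> np.ndarray:
        sub = g.genotypes[rows]
        called = sub != MISSING
        n_gametes = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_gametes > 0, alt / np.maximum(n_gametes, 1), np.nan)

    if scope == "overall":
        cols = {"overall": freq(np.arange(g.n_individuals))}
    elif scope == "per_accession":
        cols = {acc: freq(g.individuals_of(acc)) for acc in g.accession_names}
    else:
        raise GenotypeDataError(f"unknown scope {scope!r}")
    return pd.DataFrame(cols, index=g.loci.index)


def snp_density(g: GenotypeMatrix, window_bp: int = 1_000_000) -> dict:
    """Per-chromosome SNP counts and windowed densities.

    Windows are half-open ``[start, start + window_bp)`` starting at
    position 1.  Loci without a position are counted separately.
    """
    loci = g.loci
    if "chromosome" not in loci.columns or "position" not in loci.columns:
        raise GenotypeDataError("loci need chromosome and position for density")
    pos = pd.to_numeric(loci["position"], errors="coerce")
    placed = loci[pos.notna()].assign(position=pos.dropna().astype(int))
    counts = placed.groupby("chromosome", sort=False).size().to_dict()
    windows = []
    for chrom, grp in placed.groupby("chromosome", sort=False):
        idx = grp["position"] // window_bp
        for w, n in idx.value_counts().sort_index().items():
            windows.append({
                "chromosome": chrom,
                "window_start": int(w) * window_bp,
                "count": int(n),
            })
    return {
        "per_chromosome": counts,
        "windows": pd.DataFrame(windows, columns=["chromosome", "window_start", "count"]),
        "n_unplaced": int(pos.isna().sum()),
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dart_csv(g: GenotypeMatrix, matrix_path: str | Path, map_path: str | Path) -> None:
    """Write the single-row counts CSV plus the accession map CSV."""
    df = g.loci.reset_index()
    for ind, row in zip(g.individual_ids, g.genotypes):
        df[ind] = [("-" if v == MISSING else str(int(v))) for v in row]
    df.to_csv(matrix_path, index=False)
    pd.DataFrame({
        "individual_id": g.individual_ids, "accession_id": g.accessions,
    }).to_csv(map_path, index=False)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file (GT only, REF=A ALT=T placeholders)."""
    order = np.arange(g.n_loci)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = g.loci["chromosome"] if "chromosome" in g.loci.columns else pd.Series(["."] * g.n_loci, index=g.loci.index)
        for chrom in pd.unique(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.individual_ids)) + "\n")
        positions = g.loci["position"] if "position" in g.loci.columns else pd.Series([1] * g.n_loci, index=g.loci.index)
        for j in order:
            locus = g.loci.index[j]
            pos = positions.iloc[j]
            fh.write("\t".join([
                str(chroms.iloc[j]), str(int(pos) if pd.notna(pos) else 1), str(locus),
                "A", "T", ".", "PASS", ".", "GT",
                *[_GT_STR[int(v)] for v in g.genotypes[:, j]],
            ]) + "\n")


def write_phenotypes_csv(p: PhenotypeTable, path: str | Path) -> None:
    out = p.data.copy()
    out.insert(0, "accession", p.accessions)
    out.reset_index().rename(columns={"index": "individual_id"}).to_csv(path, index=False)
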