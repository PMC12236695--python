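"""Readers/writers for local-ancestry posterior tables and gene annotations.

The genetic input to every analysis in this package is a matrix of
per-marker, per-individual posterior dosages of major-parent ancestry:
for each ancestry-informative marker (AIM) and each diploid individual, a
value in [0, 1] interpreted as the posterior-weighted fraction of the
individual's two alleles at that site that descend from the major parent
species (0 = homozygous minor parent, 0.5 = heterozygous, 1 = homozygous
major parent).  A single designated mitochondrial AIM represents the
non-recombining mitogenome.

Gene annotations carry 1-based inclusive genomic intervals plus one of
three functional classes: ``interacting_nmt`` (nuclear-encoded proteins
that physically contact mitochondrially encoded gene products),
``noninteracting_nmt`` (mitochondrially targeted but not in contact), and
``non_nmt`` (everything else).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA_SENTINEL = "NA"
GENE_CLASSES = ("interacting_nmt", "noninteracting_nmt", "non_nmt")
COMPARTMENTS = ("nuclear", "mito")


class AncestryIOError(ValueError):
    """Raised on malformed posterior tables or annotations."""


@dataclass(frozen=True)
class AimSite:
    """One ancestry-informative marker."""

    chrom: str
    pos: int  # 1-based
    compartment: str  # "nuclear" | "mito"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise AncestryIOError(
                f"unknown compartment {self.compartment!r} at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval (1-based inclusive) with a functional class label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    gene_class: str

    def __post_init__(self):
        if self.start > self.end:
            raise AncestryIOError(f"gene {self.gene_id}: start > end")
        if self.gene_class not in GENE_CLASSES:
            raise AncestryIOError(
                f"gene {self.gene_id}: unknown class {self.gene_class!r}"
            )


@dataclass
class PosteriorMatrix:
    """Sites x individuals grid of ancestry dosages; NaN marks missing."""

    values: np.ndarray  # float64, shape (n_sites, n_individuals)
    individuals: list[str]
    sites: list[AimSite]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AncestryIOError("posterior matrix must be 2-dimensional")
        if self.values.shape != (len(self.sites), len(self.individuals)):
            raise AncestryIOError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise AncestryIOError("duplicate individual ids")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise AncestryIOError("duplicate (chrom, pos) among sites")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            s = self.sites[i]
            raise AncestryIOError(
                f"posterior {self.values[i, j]} outside [0,1] at "
                f"{s.chrom}:{s.pos}, individual {self.individuals[j]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        raise AncestryIOError(f"site {chrom}:{pos} not found")

    def nuclear_mask(self) -> np.ndarray:
        return np.array([s.compartment == "nuclear" for s in self.sites])

    def copy(self) -> "PosteriorMatrix":
        return PosteriorMatrix(
            self.values.copy(), list(self.individuals), list(self.sites)
        )


def _open_text(path_or_buf, mode="r"):
    if hasattr(path_or_buf, "read") or hasattr(path_or_buf, "write"):
        return path_or_buf, False
    return open(path_or_buf, mode), True


def read_posterior_table(path) -> tuple[PosteriorMatrix, list[AimSite]]:
    """Parse a posterior TSV (chrom, pos, compartment, then one column per
    individual).  Lines starting with ``#`` are metadata and skipped; the
    missing-value sentinel is ``NA``.  Values outside [0, 1] are an error
    naming the offending cell."""
    fh, close = _open_text(path)
    try:
        header = None
        rows = []
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append((lineno, fields))
    finally:
        if close:
            fh.close()
    if header is None:
        raise AncestryIOError("missing header line")
    if header[:3] != ["chrom", "pos", "compartment"]:
        raise AncestryIOError(
            "header must begin with chrom, pos, compartment; got " + "\t".join(header[:3])
        )
    individuals = header[3:]
    sites: list[AimSite] = []
    data = np.full((len(rows), len(individuals)), np.nan)
    for r, (lineno, fields) in enumerate(rows):
        if len(fields) != len(header):
            raise AncestryIOError(f"line {lineno}: expected {len(header)} fields")
        site = AimSite(fields[0], int(fields[1]), fields[2])
        sites.append(site)
        for c, tok in enumerate(fields[3:]):
            if tok == NA_SENTINEL:
                continue
            v = float(tok)
            if not 0.0 <= v <= 1.0:
                raise AncestryIOError(
                    f"value {tok} outside [0,1] at {site.chrom}:{site.pos}, "
                    f"individual {individuals[c]}"
                )
            data[r, c] = v
    m = PosteriorMatrix(data, individuals, sites)
    return m, sites


def write_posterior_table(m: PosteriorMatrix, path, header_meta: dict | None = None):
    """Write the round-trippable posterior TSV; metadata go in leading
    ``#key=value`` lines."""
    fh, close = _open_text(path, "w")
    try:
        for k, v in (header_meta or {}).items():
            fh.write(f"#{k}={v}\n")
        fh.write("\t".join(["chrom", "pos", "compartment"] + list(m.individuals)) + "\n")
        for i, s in enumerate(m.sites):
            row = [s.chrom, str(s.pos), s.compartment]
            for v in m.values[i]:
                row.append(NA_SENTINEL if np.isnan(v) else repr(float(v)))
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()


def filter_posteriors(m: PosteriorMatrix, lo: float = 0.2, hi: float = 0.8) -> PosteriorMatrix:
    """Mask low-confidence posteriors: entries strictly between ``lo`` and
    ``hi`` become missing.  Boundary values equal to the thresholds are
    retained.  Idempotent; never resurrects missing entries."""
    if not (0.0 <= lo < hi <= 1.0):
        raise AncestryIOError(f"invalid thresholds lo={lo}, hi={hi} (need 0 <= lo < hi <= 1)")
    out = m.values.copy()
    with np.errstate(invalid="ignore"):
        out[(out > lo) & (out < hi)] = np.nan
    return PosteriorMatrix(out, list(m.individuals), list(m.sites))


def map_aims_to_genes(
    sites: Sequence[AimSite], genes: Sequence[GeneAnnotation]
) -> dict[str, list[int]]:
    """Assign each AIM to every gene whose 1-based inclusive interval
    contains its position on the same chromosome.  Returns
    gene_id -> sorted site indices; genes containing no AIM are absent."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append((s.pos, i))
    for v in by_chrom.values():
        v.sort()
    mapping: dict[str, list[int]] = {}
    import bisect

    for g in genes:
        entries = by_chrom.get(g.chrom)
        if not entries:
            continue
        poss = [p for p, _ in entries]
        a = bisect.bisect_left(poss, g.start)
        b = bisect.bisect_right(poss, g.end)
        if b > a:
            mapping[g.gene_id] = sorted(entries[k][1] for k in range(a, b))
    return mapping


@dataclass
class PopulationSummary:
    mean_nuclear_ancestry: float
    mito_major_freq: float
    mito_minor_freq: float
    n_mito_called: int
    per_individual_ancestry: pd.Series  # indexed by individual id


def population_summaries(m: PosteriorMatrix, mito_calls) -> PopulationSummary:
    """Population-level summaries from a *filtered* matrix: mean nuclear
    ancestry (over non-missing nuclear entries), mito haplotype
    frequencies among called individuals, and per-individual mean nuclear
    ancestry for histogramming."""
    nuc = m.values[m.nuclear_mask()]
    if nuc.size == 0 or np.all(np.isnan(nuc)):
        raise AncestryIOError("no data: no non-missing nuclear posteriors")
    calls = np.asarray(mito_calls, dtype=float)
    called = ~np.isnan(calls)
    n_called = int(called.sum())
    major = float(np.sum(calls[called] == 1.0) / n_called) if n_called else float("nan")
    per_ind = pd.Series(np.nanmean(nuc, axis=0), index=list(m.individuals))
    return PopulationSummary(
        mean_nuclear_ancestry=float(np.nanmean(nuc)),
        mito_major_freq=major,
        mito_minor_freq=1.0 - major if n_called else float("nan"),
        n_mito_called=n_called,
        per_individual_ancestry=per_ind,
    )


GENE_TABLE_HEADER = ["chrom", "start", "end", "gene_id", "gene_class"]


def read_gene_table(path) -> list[GeneAnnotation]:
    """BED-like 5-column TSV (chrom, start, end, gene_id, gene_class) in the
    1-based inclusive dialect declared by its ``#coords`` header line."""
    fh, close = _open_text(path)
    genes = []
    try:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != GENE_TABLE_HEADER:
                    raise AncestryIOError(
                        "gene table header must be " + "\t".join(GENE_TABLE_HEADER)
                    )
                continue
            genes.append(
                GeneAnnotation(fields[3], fields[0], int(fields[1]), int(fields[2]), fields[4])
            )
    finally:
        if close:
            fh.close()
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise AncestryIOError("duplicate gene_id in gene table")
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path):
    fh, close = _open_text(path, "w")
    try:
        fh.write("#coords=1-based-inclusive\n")
        fh.write("\t".join(GENE_TABLE_HEADER) + "\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.gene_class}\n")
    finally:
        if close:
            fh.close()


def read_focal_genes(path) -> list[str]:
    """One gene_id per line; '#' comments and blanks skipped."""
    fh, close = _open_text(path)
    try:
        out = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    finally:
        if close:
            fh.close()
    return out
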