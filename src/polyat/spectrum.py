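"""Transition-type and tri-nucleotide-motif mutation spectra.

Bi-allelic SNPs fall into 6 unordered transition types (A/C, A/G, A/T, C/G,
C/T, G/T).  A motif is the SNP with its immediate 5' and 3' reference-strand
flanks, written 5'-X[N1/N2]Y-3'; there are 16 x 6 = 96 motifs.  Sites at
chromosome ends or with an N flank have no usable motif and are excluded from
motif frequencies (but kept for type-level statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import BASES, COMPLEMENT, AccessionPanel, GenotypeMatrix, Genome, SiteTable
from .sitecomp import base_sums

TRANSITION_TYPES = ("A/C", "A/G", "A/T", "C/G", "C/T", "G/T")

#: the four types whose base values can move [AT]; A/T and C/G leave it fixed
AT_CHANGING_TYPES = ("A/C", "A/G", "C/T", "G/T")


def transition_type(ref: str, alt: str) -> str:
    """Canonical unordered transition type of a ref/alt pair."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"alleles must be in {{A,C,G,T}}, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    a, b = sorted((ref, alt))
    return f"{a}/{b}"


class Motif(NamedTuple):
    """Tri-nucleotide motif: 5' flank, transition type, 3' flank."""

    left: str
    ttype: str
    right: str

    def __str__(self) -> str:
        return f"{self.left}[{self.ttype}]{self.right}"

    @classmethod
    def parse(cls, s: str) -> "Motif":
        left, rest = s[0], s[2:]
        ttype, right = rest[:-2], rest[-1]
        m = cls(left, ttype, right)
        if m.left not in BASES or m.right not in BASES or m.ttype not in TRANSITION_TYPES:
            raise ValueError(f"invalid motif string {s!r}")
        return m


def all_motifs() -> list[Motif]:
    """All 96 motifs in a fixed enumeration order."""
    return [Motif(l, t, r) for t in TRANSITION_TYPES for l, r in product(BASES, BASES)]


def motif_str(left: str, ttype: str, right: str) -> str:
    return f"{left}[{ttype}]{right}"


def revcomp_motif(m: Motif | str) -> Motif:
    """Reverse-complement pairing of motifs (an involution over all 96)."""
    if isinstance(m, str):
        m = Motif.parse(m)
    b1, b2 = m.ttype.split("/")
    return Motif(
        COMPLEMENT[m.right],
        transition_type(COMPLEMENT[b1], COMPLEMENT[b2]),
        COMPLEMENT[m.left],
    )


def motif_of(chrom: str, pos: int, ref: str, alt: str, genome: Genome) -> Motif | None:
    """Motif from the reference flanks, or None when unusable.

    Flanks are read on the forward strand at pos-1 and pos+1; chromosome-end
    sites and N flanks are unusable.
    """
    seq = genome.sequences.get(chrom)
    if seq is None:
        raise ValueError(f"genome has no chromosome {chrom!r}")
    if pos <= 1 or pos >= len(seq):
        return None
    left, right = seq[pos - 2], seq[pos]
    if left not in BASES or right not in BASES:
        return None
    return Motif(left, transition_type(ref, alt), right)


def annotate_sites(sites: SiteTable, genome: Genome) -> SiteTable:
    """Add ``type`` and ``motif`` columns (motif NaN where unusable)."""
    df = sites.df.copy()
    df["type"] = [transition_type(r, a) for r, a in zip(df["ref"], df["alt"])]
    motifs = []
    for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"]):
        m = motif_of(c, int(p), r, a, genome)
        motifs.append(str(m) if m is not None else np.nan)
    df["motif"] = motifs
    return SiteTable(df)


@dataclass
class SpectrumTable:
    """Normalized transition-type and motif frequencies."""

    type_freq: pd.Series   # index: 6 types, sums to 1
    motif_freq: pd.Series  # index: 96 motif strings, sums to 1 over usable sites
    n_sites: int
    n_usable: int          # sites with a usable motif


def spectrum_frequencies(sites: SiteTable) -> SpectrumTable:
    """Count type and motif frequencies over a (type/motif-annotated) site table."""
    df = sites.df
    if "type" not in df.columns:
        raise ValueError("sites lack a 'type' column; run annotate_sites first")
    if len(df) == 0:
        raise ValueError("no sites")
    tfreq = df["type"].value_counts(normalize=True).reindex(TRANSITION_TYPES, fill_value=0.0)
    usable = df["motif"].dropna() if "motif" in df.columns else pd.Series(dtype=object)
    order = [str(m) for m in all_motifs()]
    if len(usable):
        mfreq = usable.value_counts(normalize=True).reindex(order, fill_value=0.0)
    else:
        mfreq = pd.Series(0.0, index=order)
    return SpectrumTable(tfreq, mfreq, len(df), len(usable))


def high_frequency_motifs(table: SpectrumTable, factor: float = 1.0,
                          expected: float = 1.0 / 96.0) -> list[str]:
    """Motifs with frequency strictly greater than factor x expected."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    sel = table.motif_freq[table.motif_freq > factor * expected]
    return list(sel.index)


def per_type_base_value(geno: GenotypeMatrix, ttype: str | None = None,
                        motifs: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-accession base fractions at sites of one transition type or motif set.

    Uses the hom=1/het=0.5 weighting; the denominator is the accession's
    non-missing site count within the subset.  Rows with zero usable sites
    have NaN fractions.
    """
    df = geno.sites.df
    mask = np.ones(len(df), dtype=bool)
    if ttype is not None:
        if "type" not in df.columns:
            raise ValueError("sites lack a 'type' column")
        mask &= (df["type"] == ttype).to_numpy()
    if motifs is not None:
        if "motif" not in df.columns:
            raise ValueError("sites lack a 'motif' column")
        mask &= df["motif"].isin(list(motifs)).to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("no sites match the requested type/motif subset")
    sums, n_used = base_sums(geno, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = sums / n_used[:, None]
    out = pd.DataFrame(fracs, columns=list(BASES), index=geno.accessions)
    out["n_sites_used"] = n_used
    out["at_value"] = out["A"] + out["T"]
    out.index.name = "accession"
    return out


def motif_value_correlation(values: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between per-accession value vectors of motif columns.

    Zero-variance columns yield NaN correlations (flagged, not dropped).
    """
    if len(values) < 3:
        raise ValueError("need >= 3 accessions")
    return values.corr(method="pearson")


def motif_at_matrix(geno: GenotypeMatrix, motifs: Iterable[str]) -> pd.DataFrame:
    """Accession x motif matrix of [A&T] values (inputs to the correlation)."""
    cols = {}
    for m in motifs:
        vals = per_type_base_value(geno, motifs=[m])
        cols[m] = vals["at_value"]
    return pd.DataFrame(cols)


def group_mean_base_value(values: pd.DataFrame, panel: AccessionPanel,
                          base: str) -> pd.Series:
    """Group means of one base-fraction column from per_type_base_value."""
    groups = pd.Series({a: panel.group_of(a) for a in values.index})
    return values[base].groupby(groups).mean()
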