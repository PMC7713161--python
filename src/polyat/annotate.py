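"""Minimal 7-class SNP effect annotation against gene models.

Classes: synonymous, missense, intronic, utr, gene_proximal, intergenic and
other_genic (start/stop-disrupting or frame-anomalous CDS changes).  Every
site receives exactly one class; across multiple overlapping transcripts the
most severe effect wins (missense > synonymous > other_genic > utr >
intronic).  The genic/non-genic merge pools intergenic + gene_proximal into
non_genic and the remaining five classes into genic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import COMPLEMENT, Gene, GeneModelSet, Genome, SiteTable, Transcript

log = logging.getLogger("polyat")

ANNOTATION_CLASSES = ("intergenic", "gene_proximal", "utr", "intronic",
                      "synonymous", "missense", "other_genic")

#: most-severe-first order used to resolve multi-transcript overlaps
SEVERITY = ("missense", "synonymous", "other_genic", "utr", "intronic")

GENIC_CLASSES = frozenset({"utr", "intronic", "synonymous", "missense", "other_genic"})


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _cds_positions(tx: Transcript, strand: str) -> list[int] | None:
    """Genomic positions of the CDS in translation order, or None if len % 3 != 0."""
    if tx.cds_length() % 3 != 0:
        return None
    pos: list[int] = []
    for s, e in tx.cds:
        pos.extend(range(s, e + 1))
    if strand == "-":
        pos.reverse()
    return pos


def _codon_effect(site_pos: int, ref: str, alt: str, cds_pos: list[int],
                  chrom_seq: str, strand: str) -> str:
    """Effect of a ref->alt substitution at a CDS position."""
    i = cds_pos.index(site_pos)
    codon_i = i // 3
    codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
    bases = [chrom_seq[p - 1] for p in codon_positions]
    if strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    offset = i % 3
    if bases[offset] != ref:
        # reference genome disagrees with the VCF ref allele; trust the genome
        # for the codon context but substitute both alleles into it
        pass
    ref_codon = bases.copy()
    ref_codon[offset] = ref
    alt_codon = bases.copy()
    alt_codon[offset] = alt
    if "N" in ref_codon or "N" in alt_codon:
        return "other_genic"
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    if codon_i == 0 and "".join(ref_codon) == "ATG" and "".join(alt_codon) != "ATG":
        return "other_genic"  # start-loss
    if aa_ref == "*" or aa_alt == "*":
        if aa_ref == aa_alt:
            return "synonymous"
        return "other_genic"  # stop gain/loss
    if aa_ref == aa_alt:
        return "synonymous"
    return "missense"


def classify_site(chrom: str, pos: int, ref: str, alt: str,
                  gene_models: GeneModelSet, genome: Genome,
                  proximal_bp: int = 5000,
                  _by_chrom: dict | None = None,
                  _cds_cache: dict | None = None) -> str:
    """Classify one SNP into the 7-class annotation scheme."""
    by_chrom = _by_chrom if _by_chrom is not None else gene_models.by_chrom()
    cds_cache = _cds_cache if _cds_cache is not None else {}
    genes = by_chrom.get(chrom, [])
    effects: list[str] = []
    proximal = False
    seq = genome.sequences.get(chrom)
    for g in genes:
        if g.start - proximal_bp <= pos <= g.end + proximal_bp:
            if not (g.start <= pos <= g.end):
                proximal = True
                continue
            for tx in g.transcripts:
                key = tx.tx_id
                if key not in cds_cache:
                    cp = _cds_positions(tx, g.strand)
                    if cp is None:
                        log.warning("transcript %s CDS length not divisible by 3; skipped", tx.tx_id)
                    cds_cache[key] = cp
                cds_pos = cds_cache[key]
                if cds_pos and _in_intervals(pos, tx.cds):
                    if seq is None:
                        raise ValueError(f"genome has no sequence for chromosome {chrom!r}")
                    effects.append(_codon_effect(pos, ref, alt, cds_pos, seq, g.strand))
                elif _in_intervals(pos, tx.utr5) or _in_intervals(pos, tx.utr3):
                    effects.append("utr")
                elif _in_intervals(pos, tx.exons):
                    effects.append("utr")  # exonic non-CDS with no explicit UTR record
                else:
                    effects.append("intronic")
    if effects:
        for sev in SEVERITY:
            if sev in effects:
                return sev
    if proximal:
        return "gene_proximal"
    return "intergenic"


def classify_sites(sites: SiteTable, gene_models: GeneModelSet, genome: Genome,
                   proximal_bp: int = 5000) -> pd.Series:
    """Vector version of :func:`classify_site`; returns a Series aligned to sites."""
    by_chrom = gene_models.by_chrom()
    cds_cache: dict = {}
    df = sites.df
    out = [
        classify_site(c, int(p), r, a, gene_models, genome, proximal_bp,
                      _by_chrom=by_chrom, _cds_cache=cds_cache)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return pd.Series(out, index=df.index, name="annot_class")


def merge_sets(classes: pd.Series) -> pd.Series:
    """Partition annotation classes into {genic, non_genic}; counts conserved."""
    unknown = set(classes.unique()) - set(ANNOTATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown annotation classes {sorted(unknown)}")
    return classes.map(lambda c: "genic" if c in GENIC_CLASSES else "non_genic")


def subsample_equal(set_x: np.ndarray, set_y: np.ndarray, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw equal-size uniform subsamples (without replacement) of two index sets."""
    set_x = np.asarray(set_x)
    set_y = np.asarray(set_y)
    if len(set_x) == 0 or len(set_y) == 0:
        raise ValueError("both sets must be non-empty")
    size = min(len(set_x), len(set_y))
    rng = np.random.default_rng(seed)
    sub_x = np.sort(rng.choice(set_x, size=size, replace=False))
    sub_y = np.sort(rng.choice(set_y, size=size, replace=False))
    return sub_x, sub_y
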