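"""Focal-group-private SNPs and donor->derived mutation-rate estimation.

A site is private to the focal group (bread wheat in the motivating study)
when it is polymorphic within the focal group but every non-missing call in
the progenitor reference panels is the same homozygous allele.  That fixed
allele is the donor allele; the other is the derived (new) allele.  Derived-
allele frequencies at chosen motif subsets estimate the post-
allopolyploidization mutation rate per subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AccessionPanel, GenotypeMatrix
from .spectrum import Motif, revcomp_motif


@dataclass
class PrivateSiteTable:
    """Private sites with donor/derived allele assignment."""

    df: pd.DataFrame  # site columns + donor, derived
    focal_group_accessions: list[str]


#: progenitor panels that must be invariant, per subgenome of the focal hexaploid
DEFAULT_REFERENCE_GROUPS = {
    "A": ("wild_emmer", "durum"),
    "B": ("wild_emmer", "durum"),
    "D": ("ae_tauschii",),
}


def call_private_sites(geno: GenotypeMatrix, panel: AccessionPanel,
                       focal_groups: tuple[str, ...],
                       reference_groups: dict[str, tuple[str, ...]] | None = None,
                       max_ref_missing: float = 0.2) -> PrivateSiteTable:
    """Call focal-private SNPs against per-subgenome progenitor panels.

    Private iff (a) 0 < derived frequency < 1 over non-missing focal
    accessions and (b) all non-missing reference calls are one identical
    homozygous allele with reference missing rate <= ``max_ref_missing``.
    Heterozygous or conflicting reference calls disqualify a site.
    """
    if reference_groups is None:
        reference_groups = DEFAULT_REFERENCE_GROUPS
    focal = [a for g in focal_groups for a in panel.members(g) if a in geno.accessions]
    if not focal:
        raise ValueError("no focal accessions found")
    fidx = geno.accession_index(focal)
    sdf = geno.sites.df
    d_focal = geno.dosage[fidx]

    keep = np.zeros(len(sdf), dtype=bool)
    donor = np.empty(len(sdf), dtype=object)
    for sub in pd.unique(sdf["subgenome"]):
        if sub not in reference_groups:
            continue
        refs = [a for g in reference_groups[sub] for a in panel.members(g)
                if a in geno.accessions]
        if not refs:
            raise ValueError(f"no reference accessions for subgenome {sub!r}")
        ridx = geno.accession_index(refs)
        scols = np.flatnonzero((sdf["subgenome"] == sub).to_numpy())
        dr = geno.dosage[np.ix_(ridx, scols)]
        miss = np.isnan(dr)
        miss_rate = miss.mean(axis=0)
        any_het = np.nansum(dr == 0.5, axis=0) > 0
        n_obs = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mx = np.nanmax(np.where(miss, -np.inf, dr), axis=0)
            mn = np.nanmin(np.where(miss, np.inf, dr), axis=0)
        fixed = (n_obs > 0) & (mx == mn) & ~any_het & (miss_rate <= max_ref_missing)

        df_sub = d_focal[:, scols]
        fmiss = np.isnan(df_sub)
        with np.errstate(invalid="ignore"):
            ffreq = np.nanmean(df_sub, axis=0)
        any_obs = (~fmiss).any(axis=0)
        poly = any_obs & (ffreq > 0) & (ffreq < 1)

        ok = fixed & poly
        keep[scols[ok]] = True
        donor_allele = np.where(mx == 0.0, sdf["ref"].to_numpy()[scols],
                                sdf["alt"].to_numpy()[scols])
        donor[scols] = donor_allele

    out = sdf.loc[keep].copy()
    out["donor"] = donor[keep]
    out["derived"] = np.where(out["donor"] == out["ref"], out["alt"], out["ref"])
    return PrivateSiteTable(out.reset_index(drop=True), focal)


def derived_rate(geno: GenotypeMatrix, private_sites: PrivateSiteTable,
                 motif_set=None, donor_base: str | None = None,
                 derived_base: str | None = None) -> pd.Series:
    """Per-accession derived-allele frequency at qualifying private sites.

    The denominator is the accession's non-missing qualifying site count.
    ``motif_set`` restricts to listed motifs, ``donor_base``/``derived_base``
    to a mutation direction (e.g. C -> T).  Returns a Series over the focal
    accessions; NaN where an accession has no qualifying calls.
    """
    df = private_sites.df
    mask = np.ones(len(df), dtype=bool)
    if motif_set is not None:
        if "motif" not in df.columns:
            raise ValueError("private sites lack a 'motif' column")
        mask &= df["motif"].isin(list(motif_set)).to_numpy()
    if donor_base is not None:
        mask &= (df["donor"] == donor_base).to_numpy()
    if derived_base is not None:
        mask &= (df["derived"] == derived_base).to_numpy()
    sel = df.loc[mask]
    if len(sel) == 0:
        raise ValueError("no qualifying private sites for the requested subset")

    focal = private_sites.focal_group_accessions
    fidx = geno.accession_index(focal)
    # map (chrom,pos) back to genotype columns
    key = geno.sites.df.reset_index().set_index(["chrom", "pos"])["index"]
    cols = key.loc[list(zip(sel["chrom"], sel["pos"]))].to_numpy()
    d = geno.dosage[np.ix_(fidx, cols)]
    derived_is_alt = (sel["derived"] == sel["alt"]).to_numpy()
    dd = np.where(derived_is_alt[None, :], d, 1.0 - d)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing accession -> NaN
        rate = np.nanmean(dd, axis=1)
    return pd.Series(rate, index=focal, name="derived_rate")


def hotspot_rate_by_subgenome(geno: GenotypeMatrix, private_sites: PrivateSiteTable,
                              ct_motifs: list[str]) -> pd.DataFrame:
    """Group C->T (and strand-mirrored G->A) derived rates per subgenome.

    ``ct_motifs`` lists motifs around the C/T type; their reverse complements
    around A/G are included automatically so both strand orientations count.
    """
    ct = list(ct_motifs)
    ga = [str(revcomp_motif(Motif.parse(m))) for m in ct]
    rows = {}
    for sub in pd.unique(private_sites.df["subgenome"]):
        psub = PrivateSiteTable(
            private_sites.df[private_sites.df["subgenome"] == sub].reset_index(drop=True),
            private_sites.focal_group_accessions,
        )
        r_ct = derived_rate(geno, psub, motif_set=ct, donor_base="C", derived_base="T")
        r_ga = derived_rate(geno, psub, motif_set=ga, donor_base="G", derived_base="A")
        rows[sub] = pd.concat([r_ct, r_ga]).groupby(level=0).mean()
    return pd.DataFrame(rows)
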