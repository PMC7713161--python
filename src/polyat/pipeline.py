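"""High-level orchestration of the per-subgenome [AT]-increase analysis.

Each subgenome is analysed within the accessions that carry it: sites are
filtered (MAF >= 5%, missing rate <= 20% by default) over the carrier panel,
per-accession [AT] values are computed, and the wild -> domesticated increase
is the difference of group means (bread-wheat groups vs the wild progenitor
group of that lineage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BREAD_WHEAT_GROUPS, AccessionPanel, GenotypeMatrix, SUBGENOMES
from .sitecomp import (
    accession_composition,
    duncan_mrt,
    filter_sites,
    window_at,
    window_difference,
)

#: the wild progenitor group compared against bread wheat, per subgenome
WILD_GROUP = {"A": "wild_emmer", "B": "wild_emmer", "D": "ae_tauschii"}


@dataclass
class SubgenomeAT:
    """Per-subgenome [AT] analysis products."""

    profiles: pd.DataFrame      # accession, group, subgenome, at_value, n_sites_used
    delta_at: dict[str, float]  # subgenome -> mean(bread wheat) - mean(wild)
    n_sites: dict[str, int]
    filtered: dict[str, GenotypeMatrix]


def subgenome_at_analysis(geno: GenotypeMatrix, panel: AccessionPanel,
                          maf_min: float = 0.05, missing_max: float = 0.20,
                          subgenomes=SUBGENOMES) -> SubgenomeAT:
    """Filter, profile and compare [AT] per subgenome."""
    panel.validate_against(geno)
    profiles = []
    delta = {}
    n_sites = {}
    filtered = {}
    for sub in subgenomes:
        carriers = [a for a in geno.accessions if a in set(panel.carriers_of(sub))]
        sub_mask = (geno.sites.df["subgenome"] == sub).to_numpy()
        if not sub_mask.any():
            continue
        g = geno.subset_sites(sub_mask).subset_accessions(carriers)
        g = filter_sites(g, maf_min=maf_min, missing_max=missing_max)
        n_sites[sub] = g.n_sites
        filtered[sub] = g
        prof = accession_composition(g).df
        prof = prof.assign(
            subgenome=sub,
            group=[panel.group_of(a) for a in prof.index],
        )
        profiles.append(prof.reset_index())
        by_group = prof.groupby("group")["at_value"].mean()
        wild = WILD_GROUP[sub]
        bw = [b for b in BREAD_WHEAT_GROUPS if b in by_group.index]
        if wild in by_group.index and bw:
            delta[sub] = float(by_group[bw].mean() - by_group[wild])
    return SubgenomeAT(pd.concat(profiles, ignore_index=True), delta, n_sites, filtered)


def window_delta_by_subgenome(result: SubgenomeAT, panel: AccessionPanel,
                              lengths: dict[str, int], window: int = 2_000_000,
                              step: int = 1_000_000, min_sites: int = 10,
                              boundary: float = 0.1):
    """Window-level [AT] differences (bread wheat - wild) per subgenome.

    Returns (per-subgenome window DataFrames, per-subgenome summary dict,
    Duncan letter table comparing the three subgenomes' window deltas).
    """
    tables = {}
    summaries = {}
    deltas_by_sub = {}
    for sub, g in result.filtered.items():
        wild = WILD_GROUP[sub]
        groups = [wild] + [b for b in BREAD_WHEAT_GROUPS]
        sub_lengths = {c: L for c, L in lengths.items()
                       if c in set(g.sites.df["chrom"])}
        tracks = window_at(g, panel, groups, sub_lengths, window, step, min_sites)
        bw_df = sum(tracks[b].df["at_value"] for b in BREAD_WHEAT_GROUPS) / len(BREAD_WHEAT_GROUPS)
        dom = tracks[BREAD_WHEAT_GROUPS[0]]
        dom = type(dom)(dom.df.assign(at_value=bw_df), "bread_wheat")
        table, summary = window_difference(dom, tracks[wild], boundary=boundary)
        tables[sub] = table
        summaries[sub] = summary
        vals = table["delta_at"].dropna().to_numpy()
        if len(vals) >= 2:
            deltas_by_sub[sub] = vals
    letters = duncan_mrt(deltas_by_sub) if len(deltas_by_sub) >= 2 else None
    return tables, summaries, letters
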