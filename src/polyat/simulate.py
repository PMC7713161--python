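"""Synthetic allopolyploid-domestication datasets.

The generator emulates a hexaploid crop (subgenomes A and B from a tetraploid
progenitor, D from a diploid progenitor) sampled together with its wild
progenitor species.  Site-wise statistics, not haplotype structure, are what
the analysis pipeline measures, so no coalescent machinery is used: variants
belong to one of three strata per subgenome,

* ``standing``   -- ancestral polymorphism shared by wild and domesticated
                    groups, alternate-allele frequency ~ Beta(a, b);
* ``wild_new``   -- mutations on the wild-progenitor branch, private to the
                    wild group of that lineage;
* ``dom_new``    -- mutations on the domesticated (hexaploid) branch, private
                    to the bread-wheat groups; the per-subgenome rate
                    multiplier scales this stratum's budget (D > A = B is the
                    pattern under study).

All mutations are drawn from one context-dependent spectrum: 6 transition-
type rates with a GC->AT directional bias plus tri-nucleotide motif hotspots
(x5 for five C->T contexts and, by strand symmetry, their A/G reverse
complements).  With equal multipliers the wild and domesticated branches are
exchangeable, giving a symmetric null for the [AT]-increase statistics.

Every emitted variant is recorded in a truth ledger (stratum, donor/derived
allele, motif, drawn frequency) so recovery tests can score the pipeline
against planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    BREAD_WHEAT_GROUPS,
    DEFAULT_GROUP_SUBGENOMES,
    AccessionPanel,
    ExpressionTable,
    Gene,
    GeneModelSet,
    Genome,
    GenotypeMatrix,
    RegionSet,
    SUBGENOMES,
    Transcript,
    site_table,
    subgenome_of,
)
from .spectrum import Motif, motif_str, revcomp_motif, transition_type

_BASE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}
_STOPS = {"TAA", "TAG", "TGA"}

#: default five C->T hotspot contexts (A/G reverse complements are implied)
DEFAULT_HOTSPOTS = ("A[C/T]G", "C[C/T]A", "T[C/T]G", "G[C/T]G", "A[C/T]A")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic allopolyploid cohort."""

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {
        "1A": 2_000_000, "2A": 2_000_000,
        "1B": 2_000_000, "2B": 2_000_000,
        "1D": 2_000_000, "2D": 2_000_000,
    })
    gc_content: float = 0.46
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "wild_emmer": 15, "durum": 10, "ae_tauschii": 15,
        "landrace_east": 10, "landrace_west": 10, "variety": 15,
    })
    #: expected variant counts per subgenome
    standing_per_subgenome: int = 2500
    branch_new_per_subgenome: int = 1250
    #: domesticated-branch rate multiplier per subgenome
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 1.0, "D": 1.5})
    #: 6-type mutation rates before hotspot boosting (strand-symmetric pairs)
    type_rates: dict[str, float] = field(default_factory=lambda: {
        "A/G": 0.30, "C/T": 0.30, "A/C": 0.11, "G/T": 0.11,
        "A/T": 0.09, "C/G": 0.09,
    })
    hotspot_motifs: tuple[str, ...] = DEFAULT_HOTSPOTS
    hotspot_multiplier: float = 5.0
    #: probability that the ancestral allele of an AT-changing mutation is the
    #: G/C member (the GC->AT bias of the spectrum)
    gc_to_at_bias: float = 0.9
    standing_beta: tuple[float, float] = (2.0, 2.0)
    #: expected derived-allele dosage of branch-new variants within the branch
    derived_freq: float = 0.25
    derived_freq_by_subgenome: dict[str, float] | None = None
    bottleneck_retention: float = 0.9
    het_rate: float = 0.02
    missing_rate: float = 0.02
    #: selective-sweep plan (domesticated-branch high-[AT] clusters)
    sweeps_per_subgenome: int = 2
    sweep_width: int = 200_000
    sweep_extra_snps: int = 100
    sweep_derived_freq: float = 0.8
    #: optional causal markers making the D-subgenome [AT] value heritable
    n_causal: int = 0
    causal_beta: float = 0.3
    gene_density_per_mb: float = 5.0

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")
        if any(m <= 0 for m in self.rate_multiplier.values()):
            raise ValueError("rate multipliers must be > 0")
        if any(r < 0 for r in self.type_rates.values()):
            raise ValueError("type rates must be >= 0")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0,1]")
        for g in self.group_sizes:
            if g not in DEFAULT_GROUP_SUBGENOMES:
                raise ValueError(f"unknown group {g!r}")

    def derived_freq_of(self, sub: str) -> float:
        if self.derived_freq_by_subgenome is not None:
            return self.derived_freq_by_subgenome[sub]
        return self.derived_freq


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the truth ledger."""

    config: SimulationConfig
    genome: Genome                      # hexaploid reference
    progenitors: dict[str, Genome]      # tetraploid_AB, diploid_D
    geno: GenotypeMatrix
    panel: AccessionPanel
    sweeps: RegionSet
    truth: pd.DataFrame
    gene_models: GeneModelSet | None = None
    expression: ExpressionTable | None = None
    causal_sites: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Reference sequences


def _random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(p)
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.uint8)


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_ASCII[codes].tobytes().decode()


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return lut[raw]


def simulate_references(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, Genome]:
    """I.i.d. reference sequences at the configured GC content.

    Returns the derived hexaploid plus one genome per progenitor lineage
    (identical sequences: the reference is the shared ancestral state).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seqs = {}
    for name, length in config.chromosomes.items():
        seqs[name] = _codes_to_seq(_random_codes(length, config.gc_content, rng))
    hexaploid = Genome(dict(seqs))
    tetra = Genome({n: s for n, s in seqs.items() if subgenome_of(n) in "AB"})
    diplo = Genome({n: s for n, s in seqs.items() if subgenome_of(n) == "D"})
    return {"hexaploid": hexaploid, "tetraploid_AB": tetra, "diploid_D": diplo}


# ---------------------------------------------------------------------------
# Gene models


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    codons = ["ATG"]
    bases = "ACGT"
    for _ in range(n_codons - 2):
        while True:
            c = "".join(bases[i] for i in rng.integers(0, 4, 3))
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def simulate_gene_models(config: SimulationConfig, genome: Genome,
                         rng: np.random.Generator | None = None) -> GeneModelSet:
    """Plant non-overlapping genes and rewrite the CDS bases so every
    transcript starts with ATG, ends with a stop and has no internal stop.

    Mutates ``genome.sequences`` in place (the planted CDS codons replace the
    random background).  Gene structure per transcript: 5'UTR, 1-3 CDS exons
    split at codon boundaries, introns, 3'UTR.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes: list[Gene] = []
    for chrom, length in genome.lengths.items():
        n_genes = int(round(length / 1e6 * config.gene_density_per_mb))
        if n_genes == 0:
            continue
        seq = list(genome.sequences[chrom])
        spacing = length // (n_genes + 1)
        cursor = max(spacing // 2, 1000)
        for gi in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            utr5_len = int(rng.integers(100, 301))
            utr3_len = int(rng.integers(100, 301))
            n_exons = int(rng.integers(1, 4))
            codon_chunks = [int(rng.integers(30, 121)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(100, 401)) for _ in range(n_exons - 1)]
            cds_string = _random_cds(sum(codon_chunks), rng)

            # transcription-order segments: (kind, length)
            segments: list[tuple[str, int]] = [("utr5", utr5_len)]
            off = 0
            for k, cc in enumerate(codon_chunks):
                segments.append(("cds", 3 * cc))
                if k < n_exons - 1:
                    segments.append(("intron", intron_lens[k]))
                off += 3 * cc
            segments.append(("utr3", utr3_len))
            span = sum(l for _, l in segments)
            start = cursor
            end = start + span - 1
            if end > length - 1000:
                break
            layout = segments if strand == "+" else segments[::-1]
            pos = start
            placed = []  # (kind, gstart, gend) in genomic order
            for kind, l in layout:
                placed.append((kind, pos, pos + l - 1))
                pos += l
            # map CDS chunks (translation order) onto genomic CDS intervals
            cds_ivs = [(s, e) for kind, s, e in placed if kind == "cds"]
            tx_cds_ivs = cds_ivs if strand == "+" else cds_ivs[::-1]
            off = 0
            for s, e in tx_cds_ivs:
                chunk = cds_string[off : off + (e - s + 1)]
                off += e - s + 1
                written = chunk if strand == "+" else _revcomp(chunk)
                seq[s - 1 : e] = list(written)
            utr5_ivs = [(s, e) for kind, s, e in placed if kind == "utr5"]
            utr3_ivs = [(s, e) for kind, s, e in placed if kind == "utr3"]
            exons = _merge_adjacent(
                [(s, e) for kind, s, e in placed if kind in ("utr5", "cds", "utr3")])
            tx = Transcript(f"{chrom}g{gi:03d}.1", exons, cds_ivs, utr5_ivs, utr3_ivs)
            genes.append(Gene(f"{chrom}g{gi:03d}", chrom, strand, start, end, [tx]))
            cursor = end + max(spacing - span, 1000)
        genome.sequences[chrom] = "".join(seq)
    return GeneModelSet(genes)


def _merge_adjacent(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        if s == out[-1][1] + 1:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def simulate_expression(gene_models: GeneModelSet, rng: np.random.Generator,
                        tissues: tuple[str, ...] = ("root", "shoot")) -> ExpressionTable:
    """Log-normal TPMs per gene and tissue (some genes fall below TPM=1)."""
    ids = gene_models.gene_ids()
    data = {t: np.exp(rng.normal(0.5, 1.5, size=len(ids))) for t in tissues}
    return ExpressionTable(pd.DataFrame(data, index=pd.Index(ids, name="gene")))


# ---------------------------------------------------------------------------
# Variant placement


def _expanded_hotspots(motifs: tuple[str, ...]) -> set[tuple[str, str, str]]:
    out = set()
    for m in motifs:
        mm = Motif.parse(m)
        rc = revcomp_motif(mm)
        out.add((mm.ttype, mm.left, mm.right))
        out.add((rc.ttype, rc.left, rc.right))
    return out


_GC = {"C", "G"}


def _draw_mutations(n: int, config: SimulationConfig, rng: np.random.Generator,
                    gc_bias: float | None = None) -> pd.DataFrame:
    """Draw n mutation classes: (type, ancestral, derived) with strand flip."""
    bias = config.gc_to_at_bias if gc_bias is None else gc_bias
    types = list(config.type_rates)
    p = np.array([config.type_rates[t] for t in types], dtype=float)
    p = p / p.sum()
    t_idx = rng.choice(len(types), size=n, p=p)
    anc = np.empty(n, dtype=object)
    der = np.empty(n, dtype=object)
    u_bias = rng.random(n)
    u_flip = rng.random(n) < 0.5
    for i in range(n):
        b1, b2 = types[t_idx[i]].split("/")
        gc_member = b1 if b1 in _GC else b2
        at_member = b2 if gc_member == b1 else b1
        if (b1 in _GC) != (b2 in _GC):  # AT-changing type
            a = gc_member if u_bias[i] < bias else at_member
        else:
            a = b1 if u_bias[i] < 0.5 else b2
        d = b2 if a == b1 else b1
        if u_flip[i]:  # mutation on the minus strand
            a, d = _RC[a], _RC[d]
        anc[i], der[i] = a, d
    return pd.DataFrame({"anc": anc, "der": der})


class _PlacementSpace:
    """Per-subgenome candidate-position bookkeeping for variant placement."""

    def __init__(self, chroms: list[str], codes: dict[str, np.ndarray],
                 available: dict[str, np.ndarray]):
        self.chroms = chroms
        self.offsets = {}
        total = 0
        for c in chroms:
            self.offsets[c] = total
            total += len(codes[c])
        self.bounds = np.array([self.offsets[c] for c in chroms] + [total])
        self.codes = np.concatenate([codes[c] for c in chroms])
        self.avail = np.concatenate([available[c] for c in chroms])
        for c in chroms:  # interior positions only (flanks must exist)
            self.avail[self.offsets[c]] = False
            self.avail[self.offsets[c] + len(codes[c]) - 1] = False
        self.cand_by_base = {}
        for b, code in _CODE.items():
            cand = np.flatnonzero(self.avail & (self.codes == code))
            left = self.codes[cand - 1]
            right = self.codes[cand + 1]
            ok = (left < 4) & (right < 4)  # N flanks give no usable motif
            self.cand_by_base[b] = (cand[ok], left[ok], right[ok])

    def region_mask(self, regions: RegionSet) -> np.ndarray:
        rmask = np.zeros(len(self.codes), dtype=bool)
        for _, r in regions.df.iterrows():
            if r.chrom in self.offsets:
                o = self.offsets[r.chrom]
                rmask[o + r.start - 1 : o + r.end] = True
        return rmask

    def to_chrom_pos(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self.bounds, gpos, side="right") - 1
        chrom = np.array(self.chroms, dtype=object)[ci]
        pos = gpos - self.bounds[ci] + 1
        return chrom, pos


def _place_sites(muts: pd.DataFrame, space: _PlacementSpace,
                 hot: set[tuple[str, str, str]], mult: float,
                 rng: np.random.Generator,
                 restrict: RegionSet | None = None) -> pd.DataFrame:
    """Assign genomic positions matching each mutation's ancestral base.

    Positions are sampled without replacement with motif-hotspot weighting:
    the weights are two-valued (1 or ``mult``), so the hot/cold split of each
    batch is drawn sequentially (the exact weighted-without-replacement law)
    and members are then sampled uniformly within each class.
    """
    rmask = space.region_mask(restrict) if restrict is not None else None
    rows = []
    for (a, d), sub in muts.groupby(["anc", "der"], sort=True):
        nb = len(sub)
        ttype = transition_type(a, d)
        cand, left, right = space.cand_by_base[a]
        alive = space.avail[cand]
        if rmask is not None:
            alive = alive & rmask[cand]
        cand, left, right = cand[alive], left[alive], right[alive]
        if len(cand) < nb:
            raise ValueError(f"not enough candidate positions for {a}->{d}")
        hot_lr = np.zeros((4, 4), dtype=bool)
        for (t, l, r) in hot:
            if t == ttype:
                hot_lr[_CODE[l], _CODE[r]] = True
        is_hot = hot_lr[left, right]
        hot_idx = cand[is_hot]
        cold_idx = cand[~is_hot]
        h_rem, c_rem = len(hot_idx), len(cold_idx)
        k_hot = 0
        u = rng.random(nb)
        for i in range(nb):
            p_hot = mult * h_rem / (mult * h_rem + c_rem) if (h_rem + c_rem) else 0.0
            if u[i] < p_hot:
                k_hot += 1
                h_rem -= 1
            else:
                c_rem -= 1

        def uniform_wor(pool: np.ndarray, k: int) -> np.ndarray:
            # uniform sample without replacement via random keys (vectorized)
            keys = rng.random(len(pool))
            return pool[np.argpartition(keys, k - 1)[:k]]

        picks = []
        if k_hot:
            picks.append(uniform_wor(hot_idx, k_hot))
        if nb - k_hot:
            picks.append(uniform_wor(cold_idx, nb - k_hot))
        pick = np.concatenate(picks)
        space.avail[pick] = False
        rows.append(pd.DataFrame({"gpos": pick, "anc": a, "der": d, "type": ttype}))
    placed = pd.concat(rows, ignore_index=True)
    gpos = placed["gpos"].to_numpy()
    chrom, pos = space.to_chrom_pos(gpos)
    placed["chrom"] = chrom
    placed["pos"] = pos
    placed["motif"] = [
        motif_str("ACGT"[space.codes[g - 1]], t, "ACGT"[space.codes[g + 1]])
        for g, t in zip(gpos, placed["type"])
    ]
    return placed.drop(columns="gpos")


# ---------------------------------------------------------------------------
# Genotypes


def _draw_dosage(f, shape: tuple[int, int], het: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Mostly-homozygous dosage draws with expected dosage exactly f.

    ``f`` broadcasts against ``shape`` = (n_accessions, n_sites): a scalar, a
    per-site row vector, or a full matrix of expected dosages.  A draw is
    heterozygous with probability ``het`` and otherwise homozygous for the
    derived allele with probability (f - het/2) / (1 - het), so the expected
    dosage equals f exactly (for f within [het/2, 1 - het/2]).
    """
    f = np.broadcast_to(np.asarray(f, dtype=float), shape)
    p_hom = np.clip((f - 0.5 * het) / (1.0 - het), 0.0, 1.0)
    is_het = rng.random(shape) < het
    hom = rng.random(shape) < p_hom
    return np.where(is_het, 0.5, np.where(hom, 1.0, 0.0))


def _make_panel(config: SimulationConfig) -> AccessionPanel:
    groups = {}
    for g, n in config.group_sizes.items():
        for i in range(n):
            groups[f"{g}_{i:02d}"] = g
    return AccessionPanel(groups)


def simulate_population(config: SimulationConfig,
                        genome: Genome | None = None,
                        rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Simulate the cohort: genotypes, panel, sweeps and the truth ledger."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = simulate_references(config, rng)["hexaploid"]
    panel = _make_panel(config)
    accessions = panel.accessions
    n_acc = len(accessions)
    acc_group = np.array([panel.group_of(a) for a in accessions])
    hot = _expanded_hotspots(config.hotspot_motifs)

    codes = {c: _seq_to_codes(s) for c, s in genome.sequences.items()}
    available = {c: v != 255 for c, v in codes.items()}  # N bases unusable

    chroms_by_sub = {s: [c for c in genome.sequences if subgenome_of(c) == s]
                     for s in SUBGENOMES}

    # sweep intervals (domesticated-branch high-[AT] clusters)
    sweep_rows = []
    for sub in SUBGENOMES:
        cands = chroms_by_sub[sub]
        if not cands:
            continue
        for k in range(config.sweeps_per_subgenome):
            chrom = cands[k % len(cands)]
            length = genome.lengths[chrom]
            width = min(config.sweep_width, length // 2)
            start = int(rng.integers(1, length - width))
            sweep_rows.append({"chrom": chrom, "start": start,
                               "end": start + width - 1, "label": f"sweep_{chrom}_{k}"})
    sweeps = RegionSet(pd.DataFrame(sweep_rows)) if sweep_rows else RegionSet(
        pd.DataFrame(columns=["chrom", "start", "end", "label"]))

    all_sites = []
    all_dosage = []
    truth_rows = []
    causal_records = []
    causal_u = np.zeros(n_acc)  # latent mutation-dose shift per accession

    group_members = {g: np.flatnonzero(acc_group == g) for g in config.group_sizes}
    bw_idx = np.concatenate([group_members[g] for g in BREAD_WHEAT_GROUPS
                             if g in group_members])

    for sub in SUBGENOMES:
        chroms = chroms_by_sub[sub]
        if not chroms:
            continue
        carriers = np.flatnonzero([sub in panel.group_subgenomes[g] for g in acc_group])
        wild_group = "wild_emmer" if sub in "AB" else "ae_tauschii"
        wild_idx = group_members.get(wild_group, np.array([], dtype=int))

        n_standing = config.standing_per_subgenome
        n_wild = config.branch_new_per_subgenome
        n_dom = int(round(config.branch_new_per_subgenome * config.rate_multiplier[sub]))
        n_total = n_standing + n_wild + n_dom

        muts = _draw_mutations(n_total, config, rng)
        space = _PlacementSpace(chroms, codes, available)
        placed = _place_sites(muts, space, hot, config.hotspot_multiplier, rng)
        strata = np.array(["standing"] * n_standing + ["wild_new"] * n_wild
                          + ["dom_new"] * n_dom)
        rng.shuffle(strata)
        placed["stratum"] = strata

        if config.sweep_extra_snps and len(sweeps):
            sub_sweeps = RegionSet(
                sweeps.df[sweeps.df["chrom"].isin(chroms)].reset_index(drop=True))
            if len(sub_sweeps):
                n_sw = config.sweep_extra_snps * len(sub_sweeps)
                muts_sw = _draw_mutations(n_sw, config, rng, gc_bias=1.0)
                placed_sw = _place_sites(muts_sw, space, hot,
                                         config.hotspot_multiplier, rng,
                                         restrict=sub_sweeps)
                placed_sw["stratum"] = "sweep_new"
                placed = pd.concat([placed, placed_sw], ignore_index=True)

        f_branch = config.derived_freq_of(sub)
        dosage = np.full((n_acc, len(placed)), np.nan)
        freqs = np.full(len(placed), np.nan)
        stratum = placed["stratum"].to_numpy()

        # --- standing variants
        st = np.flatnonzero(stratum == "standing")
        a, b = config.standing_beta
        p_st = rng.beta(a, b, size=len(st))
        freqs[st] = p_st
        carrier_set = set(carriers.tolist())
        for g, members in group_members.items():
            if sub not in panel.group_subgenomes[g]:
                continue
            dosage[np.ix_(members, st)] = _draw_dosage(
                p_st[None, :], (len(members), len(st)), config.het_rate, rng)
        # domestication bottlenecks: bread wheat (one lineage) and durum fix a
        # fraction (1 - retention) of standing variants
        for lineage in (bw_idx, group_members.get("durum", np.array([], dtype=int))):
            lineage_carr = np.array([i for i in lineage if i in carrier_set], dtype=int)
            if len(lineage_carr) == 0:
                continue
            fixed = rng.random(len(st)) > config.bottleneck_retention
            fix_val = (rng.random(len(st)) < p_st).astype(float)
            cols = st[fixed]
            dosage[np.ix_(lineage_carr, cols)] = np.broadcast_to(
                fix_val[fixed][None, :], (len(lineage_carr), len(cols)))

        # --- wild-branch new variants (private to the wild progenitor group)
        wn = np.flatnonzero(stratum == "wild_new")
        freqs[wn] = f_branch
        dosage[np.ix_(carriers, wn)] = 0.0
        if len(wild_idx):
            dosage[np.ix_(wild_idx, wn)] = _draw_dosage(
                f_branch, (len(wild_idx), len(wn)), config.het_rate, rng)

        # --- domesticated-branch new variants (private to bread wheat); the
        # subgenome rate multiplier scales both the site count and the
        # accumulated derived dosage per lineage
        dn = np.flatnonzero(np.isin(stratum, ["dom_new", "sweep_new"]))
        f_dom = min(f_branch * config.rate_multiplier[sub], 0.95)
        f_dn = np.where(stratum[dn] == "sweep_new", config.sweep_derived_freq, f_dom)
        freqs[dn] = f_dn
        dosage[np.ix_(carriers, dn)] = 0.0
        if config.n_causal and sub == "D":
            f_acc = np.clip(f_dn[None, :] * (1.0 + causal_u[bw_idx, None]), 0.0, 1.0)
        else:
            f_acc = np.broadcast_to(f_dn[None, :], (len(bw_idx), len(dn)))
        dosage[np.ix_(bw_idx, dn)] = _draw_dosage(
            f_acc, (len(bw_idx), len(dn)), config.het_rate, rng)

        # causal markers live among A/B standing variants and shift the
        # latent mutation dose used by later (D) domesticated-branch draws
        if config.n_causal and sub == "A" and len(st):
            picks = rng.choice(st, size=min(config.n_causal, len(st)), replace=False)
            for j in picks:
                x = dosage[:, j].copy()
                x[np.isnan(x)] = np.nanmean(x)
                xs = (x - x.mean()) / (x.std() + 1e-12)
                causal_u += config.causal_beta * xs
                causal_records.append({"chrom": placed["chrom"].iat[j],
                                       "pos": int(placed["pos"].iat[j]),
                                       "beta": config.causal_beta})

        # missingness
        miss = rng.random(dosage.shape) < config.missing_rate
        carrier_mask = np.zeros((n_acc, 1), dtype=bool)
        carrier_mask[carriers] = True
        dosage[miss & carrier_mask] = np.nan

        placed["subgenome"] = sub
        placed["freq"] = freqs
        all_sites.append(placed)
        all_dosage.append(dosage)

    sites = pd.concat(all_sites, ignore_index=True)
    dosage = np.concatenate(all_dosage, axis=1)

    # drop sites monomorphic in the emitted calls (a VCF would not contain them)
    with np.errstate(invalid="ignore", all="ignore"):
        mx = np.nanmax(dosage, axis=0)
        mn = np.nanmin(dosage, axis=0)
    poly = (~np.isnan(mx)) & ((mx > mn) | (mx == 0.5))
    sites = sites.loc[poly].reset_index(drop=True)
    dosage = dosage[:, poly]

    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosage = dosage[:, order]

    stable = site_table(
        sites["chrom"], sites["pos"], sites["anc"], sites["der"],
        subgenome=sites["subgenome"],
        type=sites["type"], motif=sites["motif"],
    )
    geno = GenotypeMatrix(accessions, stable, dosage)

    truth = sites.rename(columns={"anc": "ref", "der": "alt"}).copy()
    truth["donor"] = np.where(truth["stratum"] == "standing", pd.NA, truth["ref"])
    truth["derived"] = np.where(truth["stratum"] == "standing", pd.NA, truth["alt"])

    progenitors = {
        "tetraploid_AB": Genome({n: s for n, s in genome.sequences.items()
                                 if subgenome_of(n) in "AB"}),
        "diploid_D": Genome({n: s for n, s in genome.sequences.items()
                             if subgenome_of(n) == "D"}),
    }
    return SimulatedDataset(
        config=config, genome=genome,
        progenitors=progenitors, geno=geno, panel=panel, sweeps=sweeps, truth=truth,
        causal_sites=pd.DataFrame(causal_records) if causal_records else None,
    )


def simulate_dataset(config: SimulationConfig, with_genes: bool = True) -> SimulatedDataset:
    """References + (optionally) gene models and expression + population."""
    rng = np.random.default_rng(config.seed)
    genomes = simulate_references(config, rng)
    hexa = genomes["hexaploid"]
    gene_models = None
    expression = None
    if with_genes:
        gene_models = simulate_gene_models(config, hexa, rng)
        expression = simulate_expression(gene_models, rng)
        # re-derive progenitor views from the gene-planted sequences
        genomes = {
            "hexaploid": hexa,
            "tetraploid_AB": Genome({n: s for n, s in hexa.sequences.items()
                                     if subgenome_of(n) in "AB"}),
            "diploid_D": Genome({n: s for n, s in hexa.sequences.items()
                                 if subgenome_of(n) == "D"}),
        }
    ds = simulate_population(config, genome=hexa, rng=rng)
    ds.progenitors = {k: v for k, v in genomes.items() if k != "hexaploid"}
    ds.gene_models = gene_models
    ds.expression = expression
    return ds
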