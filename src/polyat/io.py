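"""Typed readers/writers and the shared data model.

Coordinates are 1-based inclusive internally (VCF convention); BED files are
converted on read/write.  Genotype dosage is the alternate-allele fraction of a
diploid call: 0 (hom ref), 0.5 (het), 1 (hom alt) or NaN (missing).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("polyat")

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBGENOMES = ("A", "B", "D")
UNASSIGNED = "unassigned"

#: default chromosome naming: optional "chr" prefix, group number 1-7, subgenome letter
DEFAULT_CHROM_PATTERN = r"^(?:chr)?[1-7]([ABD])$"

#: which subgenomes each panel group carries (hexaploid bread wheat and its
#: tetraploid (AABB) and diploid (DD) progenitor species)
DEFAULT_GROUP_SUBGENOMES = {
    "wild_emmer": frozenset("AB"),
    "durum": frozenset("AB"),
    "ae_tauschii": frozenset("D"),
    "landrace_east": frozenset("ABD"),
    "landrace_west": frozenset("ABD"),
    "variety": frozenset("ABD"),
}

#: the hexaploid focal-species groups
BREAD_WHEAT_GROUPS = ("landrace_east", "landrace_west", "variety")


class ParseError(ValueError):
    """Raised when an input file is malformed."""


def subgenome_of(chrom: str, pattern: str = DEFAULT_CHROM_PATTERN) -> str:
    """Map a chromosome name to its subgenome letter (A/B/D).

    Names that do not match ``pattern`` are routed to the ``"unassigned"``
    bucket, never dropped.
    """
    m = re.match(pattern, chrom)
    if m is None:
        return UNASSIGNED
    return m.group(1)


# ---------------------------------------------------------------------------
# Genome / FASTA


@dataclass
class Genome:
    """Reference sequences, uppercase over the {A,C,G,T,N} alphabet."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"region {chrom}:{start}-{end} outside sequence of length {len(seq)}")
        return seq[start - 1 : end]

    def base_at(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]


_VALID = set("ACGTN")
_AMBIGUOUS = set("RYSWKMBDHVU")


def read_genome(path, ambiguous: str = "N") -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase (soft-masked) bases are folded to uppercase.  IUPAC ambiguity
    codes other than N are mapped to N when ``ambiguous="N"`` (default) or
    rejected when ``ambiguous="reject"``.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"duplicate chromosome {record.id!r}")
        seq = str(record.seq).upper()
        extra = set(seq) - _VALID
        if extra:
            if ambiguous == "reject" or not extra <= _AMBIGUOUS:
                raise ParseError(f"invalid bases {sorted(extra)} in record {record.id!r}")
            seq = "".join(b if b in _VALID else "N" for b in seq)
        sequences[record.id] = seq
    if not sequences:
        raise ParseError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_genome(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SiteTable / GenotypeMatrix / VCF

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "subgenome"]


@dataclass
class SiteTable:
    """Per-SNP records, sorted by (chrom, pos), unique positions.

    ``df`` columns: chrom, pos (1-based), ref, alt, subgenome, and optionally
    ``type`` (transition type), ``motif`` and ``annot_class``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"SiteTable missing columns {missing}")
        if len(df):
            if (df["ref"] == df["alt"]).any():
                raise ValueError("SiteTable has ref == alt records")
            bad = ~(df["ref"].isin(BASES) & df["alt"].isin(BASES))
            if bad.any():
                raise ValueError("SiteTable alleles must be in {A,C,G,T}")
            if (df["pos"] < 1).any():
                raise ValueError("positions must be >= 1")
            if df.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate (chrom, pos) in SiteTable")
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SiteTable":
        return SiteTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def subset_idx(self, idx) -> "SiteTable":
        return SiteTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


def site_table(chrom, pos, ref, alt, subgenome=None, **extra) -> SiteTable:
    """Build a :class:`SiteTable`; subgenome is derived from chrom when omitted."""
    df = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64), "ref": ref, "alt": alt})
    if subgenome is None:
        df["subgenome"] = [subgenome_of(c) for c in df["chrom"]]
    else:
        df["subgenome"] = subgenome
    for k, v in extra.items():
        df[k] = v
    return SiteTable(df)


@dataclass
class GenotypeMatrix:
    """Accessions x sites alternate-allele dosage in {0, 0.5, 1, NaN}."""

    accessions: list[str]
    sites: SiteTable
    dosage: np.ndarray  # float64, shape (n_accessions, n_sites)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accessions), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.accessions)}, {len(self.sites)})"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 0.5, 1.0)).all():
            raise ValueError("dosage values must be in {0, 0.5, 1, NaN}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def accession_index(self, names) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in genotype matrix") from None

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        # keep dosage aligned with the (chrom, pos)-sorted SiteTable
        sub = self.sites.df.iloc[idx]
        order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
        idx = idx[order]
        return GenotypeMatrix(list(self.accessions), self.sites.subset_idx(idx), self.dosage[:, idx])

    def subset_accessions(self, names) -> "GenotypeMatrix":
        idx = self.accession_index(names)
        return GenotypeMatrix([self.accessions[i] for i in idx], self.sites, self.dosage[idx])


def read_genotypes(path, biallelic_only: bool = True,
                   chrom_pattern: str = DEFAULT_CHROM_PATTERN) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    GT 0/0 -> 0, 0/1 or 1/0 -> 0.5, 1/1 -> 1, ./. -> NaN.  Phased calls are
    treated as unphased.  Multi-allelic and indel records are skipped with a
    logged count when ``biallelic_only`` (always true in this implementation).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    n_skipped = 0
    for v in vcf:
        if not v.FORMAT or "GT" not in v.FORMAT:
            raise ParseError(f"record {v.CHROM}:{v.POS} has no GT field")
        alt_alleles = v.ALT
        if len(alt_alleles) != 1 or len(v.REF) != 1 or len(alt_alleles[0]) != 1 \
                or v.REF not in BASES or alt_alleles[0] not in BASES:
            n_skipped += 1
            continue
        geno = v.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(accessions))
        for i, g in enumerate(geno):
            a = g[:-1]
            if len(a) == 0 or any(x < 0 for x in a):
                dos[i] = np.nan
            else:
                dos[i] = sum(a) / len(a)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(alt_alleles[0])
        rows.append(dos)
    if n_skipped:
        log.info("read_genotypes: skipped %d multi-allelic/indel records", n_skipped)
    if rows:
        # sort records by (chrom, pos) so sites and dosage stay aligned
        order = np.lexsort((np.asarray(poss), np.asarray(chroms)))
        take = lambda xs: [xs[i] for i in order]
        chroms, poss, refs, alts = take(chroms), take(poss), take(refs), take(alts)
        dosage = np.array(rows)[order].T
    else:
        dosage = np.empty((len(accessions), 0))
    sites = site_table(
        chroms, poss, refs, alts,
        subgenome=[subgenome_of(c, chrom_pattern) for c in chroms],
    )
    return GenotypeMatrix(accessions, sites, dosage)


_GT_STR = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


def write_genotypes(geno: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 (GT only)."""
    df = geno.sites.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyat\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in pd.unique(df["chrom"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.accessions) + "\n")
        for j in range(len(df)):
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_STR[d] for d in geno.dosage[:, j]
            )
            fh.write(f"{df.chrom.iat[j]}\t{df.pos.iat[j]}\t.\t{df.ref.iat[j]}\t"
                     f"{df.alt.iat[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# AccessionPanel


@dataclass
class AccessionPanel:
    """Accession -> group labels plus the subgenomes each group carries."""

    groups: dict[str, str]  # accession -> group
    group_subgenomes: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SUBGENOMES)
    )

    def __post_init__(self) -> None:
        for g in set(self.groups.values()):
            if g not in self.group_subgenomes:
                raise ValueError(f"group {g!r} has no subgenome (ploidy) assignment")

    @property
    def accessions(self) -> list[str]:
        return list(self.groups)

    def group_of(self, accession: str) -> str:
        return self.groups[accession]

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.groups.items() if g == group]

    def carriers_of(self, subgenome: str) -> list[str]:
        """Accessions whose species carries the given subgenome."""
        return [a for a, g in self.groups.items() if subgenome in self.group_subgenomes[g]]

    def validate_against(self, geno: GenotypeMatrix) -> None:
        missing = [a for a in geno.accessions if a not in self.groups]
        if missing:
            raise ValueError(f"accessions missing from panel: {missing[:5]}...")


def read_panel(path, group_subgenomes: dict | None = None) -> AccessionPanel:
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "group"} <= set(df.columns):
        raise ParseError("panel TSV needs columns: accession, group")
    kwargs = {} if group_subgenomes is None else {"group_subgenomes": group_subgenomes}
    return AccessionPanel(dict(zip(df["accession"].astype(str), df["group"].astype(str))), **kwargs)


def write_panel(panel: AccessionPanel, path) -> None:
    pd.DataFrame(
        {"accession": list(panel.groups), "group": list(panel.groups.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RegionSet / BED


@dataclass
class RegionSet:
    """Named intervals, 1-based inclusive internally (BED is converted on read/write)."""

    df: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"RegionSet missing column {c}")
        if "label" not in df.columns:
            df["label"] = [f"region{i}" for i in range(len(df))]
        if len(df) and (df["start"] > df["end"]).any():
            raise ValueError("RegionSet has start > end")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def check_within(self, lengths: dict[str, int]) -> None:
        for _, r in self.df.iterrows():
            if r.chrom not in lengths or r.start < 1 or r.end > lengths[r.chrom]:
                raise ValueError(f"region {r.chrom}:{r.start}-{r.end} out of chromosome bounds")

    def contains(self, chrom, pos) -> np.ndarray:
        """Boolean membership for vectors of (chrom, pos)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        inside = np.zeros(len(pos), dtype=bool)
        for _, r in self.df.iterrows():
            inside |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
        return inside


def read_bed(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"],
                     usecols=[0, 1, 2, 3], dtype={0: str})
    if df[["start", "end"]].isna().any().any():
        raise ParseError(f"malformed BED file {path}")
    if (df["start"] >= df["end"]).any():
        raise ParseError("BED intervals must have start < end (0-based half-open)")
    df["start"] = df["start"].astype(np.int64) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    df["label"] = df["label"].fillna("region")
    return RegionSet(df)


def write_bed(regions: RegionSet, path) -> None:
    out = regions.df.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end", "label"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene models / GFF3


@dataclass
class Transcript:
    tx_id: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GeneModelSet:
    genes: list[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            for tx in g.transcripts:
                ex = sorted(tx.exons)
                for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                    if s2 <= e1:
                        raise ValueError(f"overlapping exons in {tx.tx_id}")

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for v in out.values():
            v.sort(key=lambda g: g.start)
        return out

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


_FEAT_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path) -> GeneModelSet:
    """Read gene models (gene/mRNA/exon/CDS/UTR features) from GFF3."""
    genes: dict[str, Gene] = {}
    transcripts: dict[str, tuple[str, Transcript]] = {}  # tx_id -> (gene_id, tx)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"malformed GFF3 at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            start, end = int(start), int(end)
            a = dict(_FEAT_ATTR.findall(attrs))
            if ftype == "gene":
                genes[a["ID"]] = Gene(a["ID"], chrom, strand, start, end)
            elif ftype == "mRNA":
                tx = Transcript(a["ID"], [], [])
                transcripts[a["ID"]] = (a["Parent"], tx)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a["Parent"]
                if parent not in transcripts:
                    raise ParseError(f"feature with unknown Parent {parent!r} at line {lineno}")
                tx = transcripts[parent][1]
                target = {"exon": tx.exons, "CDS": tx.cds,
                          "five_prime_UTR": tx.utr5, "three_prime_UTR": tx.utr3}[ftype]
                target.append((start, end))
    for tx_id, (gene_id, tx) in transcripts.items():
        tx.exons.sort(); tx.cds.sort(); tx.utr5.sort(); tx.utr3.sort()
        genes[gene_id].transcripts.append(tx)
    return GeneModelSet(list(genes.values()))


def write_gff3(models: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models.genes:
            fh.write(f"{g.chrom}\tpolyat\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for tx in g.transcripts:
                fh.write(f"{g.chrom}\tpolyat\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                         f"ID={tx.tx_id};Parent={g.gene_id}\n")
                for s, e in tx.exons:
                    fh.write(f"{g.chrom}\tpolyat\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tx.tx_id}\n")
                for s, e in tx.utr5:
                    fh.write(f"{g.chrom}\tpolyat\tfive_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tx.tx_id}\n")
                # CDS phase: computed from running length in translation order
                cds = tx.cds if g.strand == "+" else list(reversed(tx.cds))
                run = 0
                phased = []
                for s, e in cds:
                    phased.append((s, e, (3 - run % 3) % 3))
                    run += e - s + 1
                for s, e, ph in sorted(phased):
                    fh.write(f"{g.chrom}\tpolyat\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\tParent={tx.tx_id}\n")
                for s, e in tx.utr3:
                    fh.write(f"{g.chrom}\tpolyat\tthree_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tx.tx_id}\n")


# ---------------------------------------------------------------------------
# Expression table


@dataclass
class ExpressionTable:
    """Gene x tissue TPM matrix."""

    df: pd.DataFrame  # index: gene, columns: tissues

    def __post_init__(self) -> None:
        if len(self.df) and (self.df.values < 0).any():
            raise ValueError("TPM values must be >= 0")

    def tpm(self, gene: str, tissue: str) -> float:
        if gene not in self.df.index:
            return 0.0
        return float(self.df.loc[gene, tissue])


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "tissue", "tpm"} <= set(df.columns):
        raise ParseError("expression TSV needs columns: gene, tissue, tpm")
    return ExpressionTable(df.pivot_table(index="gene", columns="tissue", values="tpm"))


def write_expression(expr: ExpressionTable, path) -> None:
    long = expr.df.stack().rename("tpm").reset_index()
    long.columns = ["gene", "tissue", "tpm"]
    long.to_csv(path, sep="\t", index=False)
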