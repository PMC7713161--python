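"""Base composition of genome sequences: counts, PR2 deviation, shuffling test.

The second parity rule (PR2) states that within a single DNA strand [A] ~ [T]
and [C] ~ [G].  The [AT] value is the fraction of counted bases that are A or
T; N bases are reported but excluded from all fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Genome, RegionSet, subgenome_of

#: resampling sizes above this are scaled down (whole-genome shuffles of
#: billions of bases carry no extra information for a 100-replicate t test)
SAMPLE_CAP = 100_000_000


@dataclass
class BaseCounts:
    """Exact counts of the four bases and N within one scope."""

    nA: int
    nC: int
    nG: int
    nT: int
    nN: int = 0
    scope: str = ""

    @property
    def total(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.nN

    @property
    def acgt(self) -> int:
        return self.nA + self.nC + self.nG + self.nT

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.nA + other.nA, self.nC + other.nC,
                          self.nG + other.nG, self.nT + other.nT,
                          self.nN + other.nN, self.scope)


_ORDER = "ACGTN"


def _count_seq(seq: str, scope: str = "") -> BaseCounts:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = {b: int((arr == b.encode()).sum()) for b in _ORDER}
    return BaseCounts(n["A"], n["C"], n["G"], n["T"], n["N"], scope)


def count_bases(genome: Genome, regions: RegionSet | None = None,
                by: str = "chromosome") -> dict[str, BaseCounts]:
    """Count bases per scope.

    ``by`` is one of ``chromosome``, ``subgenome`` or ``genome``; when
    ``regions`` is given, counts are per region label instead.
    """
    if regions is not None:
        regions.check_within(genome.lengths)
        out: dict[str, BaseCounts] = {}
        for _, r in regions.df.iterrows():
            c = _count_seq(genome.fetch(r.chrom, r.start, r.end), r.label)
            out[r.label] = out[r.label] + c if r.label in out else c
        return out
    per_chrom = {name: _count_seq(seq, name) for name, seq in genome.sequences.items()}
    if by == "chromosome":
        return per_chrom
    if by == "subgenome":
        out = {}
        for name, c in per_chrom.items():
            key = subgenome_of(name)
            c = BaseCounts(c.nA, c.nC, c.nG, c.nT, c.nN, key)
            out[key] = out[key] + c if key in out else c
        return out
    if by == "genome":
        total = BaseCounts(0, 0, 0, 0, 0, "genome")
        for c in per_chrom.values():
            total = total + c
        return {"genome": total}
    raise ValueError(f"unknown scope {by!r}")


def at_fraction(counts: BaseCounts) -> float:
    """(nA + nT) / (nA + nC + nG + nT); NaN for an all-N scope."""
    if counts.acgt == 0:
        return float("nan")
    return (counts.nA + counts.nT) / counts.acgt


def pr2_deviation(counts: BaseCounts) -> tuple[float, float]:
    """Signed parity deviations (dAT, dCG) = ([A]-[T], [C]-[G])."""
    if counts.acgt == 0:
        return (float("nan"), float("nan"))
    tot = counts.acgt
    return ((counts.nA - counts.nT) / tot, (counts.nC - counts.nG) / tot)


def shuffle_at_test(counts_x: BaseCounts, counts_y: BaseCounts,
                    n_iter: int = 100, sample_size: int = 1_000_000,
                    seed: int = 0, equal_var: bool = True) -> float:
    """Bootstrap-shuffling significance test for an [AT] difference.

    For each side, draw ``n_iter`` multinomial bootstrap replicates of
    ``sample_size`` base labels from the composition implied by the counts,
    compute the replicate [AT] values, and compare the two replicate sets with
    an independent two-sample t test (equal-variance by default; Welch with
    ``equal_var=False``).  Deterministic under ``seed``.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    sample_size = int(min(sample_size, SAMPLE_CAP))
    rng = np.random.default_rng(seed)

    def replicates(c: BaseCounts) -> np.ndarray:
        if c.acgt == 0:
            raise ValueError(f"scope {c.scope!r} has no A/C/G/T bases")
        if sample_size > c.total:
            raise ValueError("sample_size exceeds available bases")
        p = np.array([c.nA, c.nC, c.nG, c.nT], dtype=float) / c.acgt
        draws = rng.multinomial(sample_size, p, size=n_iter)
        return (draws[:, 0] + draws[:, 3]) / sample_size

    x = replicates(counts_x)
    y = replicates(counts_y)
    if x.std() == 0 and y.std() == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)
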