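"""Per-accession base composition across polymorphic sites.

The counting rule: at each bi-allelic SNP an accession contributes weight 1 to
its homozygous base, or 0.5 to each of ref and alt when heterozygous; missing
calls contribute nothing and are excluded from the denominator.  The per-
accession [AT] value is (sumA + sumT) / (sumA + sumC + sumG + sumT).

Group comparisons use an F-protected Duncan multiple range test; window scans
use 2-Mb windows sliding by 1 Mb by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import BASES, AccessionPanel, GenotypeMatrix, RegionSet

log = logging.getLogger("polyat")


@lru_cache(maxsize=4096)
def _srange_ppf(q: float, p: int, df: int) -> float:
    """Cached studentized-range quantile (the ppf is expensive)."""
    return float(stats.studentized_range.ppf(q, p, df))


# ---------------------------------------------------------------------------
# Site-level statistics and filtering


def site_stats(geno: GenotypeMatrix, within: list[str] | None = None) -> pd.DataFrame:
    """Per-site minor allele frequency and missing rate.

    Allele frequency is the mean dosage over non-missing accessions (optionally
    restricted to ``within``); maf = min(f, 1-f).  A site missing in all
    accessions has maf NaN and missing_rate 1.
    """
    d = geno.dosage
    if within is not None:
        if len(within) == 0:
            raise ValueError("accession subset is empty")
        d = d[geno.accession_index(within)]
    n = d.shape[0]
    n_missing = np.isnan(d).sum(axis=0)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing sites -> NaN
        f = np.nanmean(d, axis=0)
    maf = np.minimum(f, 1.0 - f)
    return pd.DataFrame({"maf": maf, "missing_rate": n_missing / n})


def filter_sites(geno: GenotypeMatrix, maf_min: float = 0.05,
                 missing_max: float = 0.20,
                 within: list[str] | None = None) -> GenotypeMatrix:
    """Keep sites with maf >= maf_min and missing_rate <= missing_max."""
    if not (0 <= maf_min <= 1 and 0 <= missing_max <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    st = site_stats(geno, within=within)
    low_maf = ~(st["maf"] >= maf_min)  # NaN maf counts as removed
    high_miss = st["missing_rate"] > missing_max
    keep = ~(low_maf | high_miss)
    log.info("filter_sites: removed %d (maf<%g) and %d (missing>%g) of %d sites",
             int(low_maf.sum()), maf_min, int((high_miss & ~low_maf).sum()),
             missing_max, len(st))
    if not keep.any():
        log.warning("filter_sites: no sites survive filtering")
    return geno.subset_sites(keep.to_numpy())


# ---------------------------------------------------------------------------
# Accession composition profiles


@dataclass
class CompositionProfile:
    """Weighted base sums and [AT] values per accession over one site subset."""

    df: pd.DataFrame  # index accession; sumA..sumT, n_sites_used, at_value + fractions
    scope: str = ""


def _one_hot(bases: pd.Series) -> np.ndarray:
    arr = np.zeros((len(bases), 4))
    for k, b in enumerate(BASES):
        arr[:, k] = (bases == b).to_numpy()
    return arr


def base_sums(geno: GenotypeMatrix, site_idx=None) -> tuple[np.ndarray, np.ndarray]:
    """Dosage-weighted per-accession base sums.

    Returns (sums, n_used): sums has shape (n_accessions, 4) in A,C,G,T order;
    n_used is the count of non-missing sites per accession.  For every
    accession, sums.sum(axis=1) == n_used (the weights conserve mass).
    """
    if site_idx is not None:
        geno = geno.subset_sites(np.asarray(site_idx))
    d = geno.dosage
    miss = np.isnan(d)
    d0 = np.where(miss, 0.0, d)
    used = (~miss).astype(float)
    ref_hot = _one_hot(geno.sites.df["ref"])
    alt_hot = _one_hot(geno.sites.df["alt"])
    sums = (used * (1.0 - d0)) @ ref_hot + (used * d0) @ alt_hot
    return sums, used.sum(axis=1)


def accession_composition(geno: GenotypeMatrix, site_idx=None,
                          scope: str = "") -> CompositionProfile:
    """Per-accession composition profile over the given site subset.

    at_value is NaN for an accession with zero non-missing sites.
    """
    sums, n_used = base_sums(geno, site_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = sums / n_used[:, None]
        at = (sums[:, 0] + sums[:, 3]) / n_used
    at[n_used == 0] = np.nan
    df = pd.DataFrame(sums, columns=[f"sum{b}" for b in BASES], index=geno.accessions)
    df["n_sites_used"] = n_used
    for k, b in enumerate(BASES):
        df[f"frac{b}"] = fracs[:, k]
    df["at_value"] = at
    df.index.name = "accession"
    return CompositionProfile(df, scope)


def group_summary(profile: CompositionProfile, panel: AccessionPanel,
                  value: str = "at_value") -> pd.DataFrame:
    """Per-group mean/sd/CI95 of a profile column (raw values stay in profile.df)."""
    df = profile.df.copy()
    df["group"] = [panel.group_of(a) for a in df.index]
    rows = []
    for group, sub in df.groupby("group", sort=False):
        vals = sub[value].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            raise ValueError(f"group {group!r} has no accessions with defined {value}")
        mean = vals.mean()
        sd = vals.std(ddof=1) if n > 1 else np.nan
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n) if n > 1 else np.nan
        rows.append({"group": group, "n": n, "mean": mean, "sd": sd,
                     "ci95_low": mean - half, "ci95_high": mean + half})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def duncan_mrt(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """F-protected Duncan multiple range test with compact letter display.

    Groups are sorted by mean; a pair spanning p ordered means is significantly
    different when its mean difference exceeds the least significant range
    R_p = q(1 - alpha_p; p, df) * sqrt(MSE / n_h), with the Duncan protection
    level alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic mean group size.
    The range procedure is step-down: ranges inside an accepted (non-
    significant) span are not tested.  When the one-way ANOVA F test is not
    significant at ``alpha`` all groups share a single letter.

    Returns a DataFrame indexed by group with columns n, mean, letters.
    """
    names = list(values_by_group)
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 groups")
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    ns = np.array([len(g) for g in groups])
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    means = np.array([g.mean() for g in groups])
    N = ns.sum()
    df_err = N - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err

    order = np.argsort(-means)  # descending
    sorted_means = means[order]

    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)

    if mse <= 0:
        # zero error variance: any two unequal means differ
        for i in range(k):
            for j in range(k):
                if means[order[i]] == means[order[j]]:
                    nonsig[i, j] = True
    else:
        ms_between = (ns * (means - (np.concatenate(groups)).mean()) ** 2).sum() / (k - 1)
        f_p = stats.f.sf(ms_between / mse, k - 1, df_err)
        if f_p >= alpha:
            nonsig[:, :] = True
        else:
            n_h = k / (1.0 / ns).sum()
            crit = {}
            for p in range(2, k + 1):
                alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
                q = _srange_ppf(1.0 - alpha_p, p, int(df_err))
                crit[p] = q * np.sqrt(mse / n_h)

            visited: set[tuple[int, int]] = set()

            def test(i: int, j: int) -> None:
                if j <= i or (i, j) in visited:
                    return
                visited.add((i, j))
                if nonsig[i, j]:  # already inside an accepted span
                    return
                span = j - i + 1
                if sorted_means[i] - sorted_means[j] <= crit[span]:
                    nonsig[i : j + 1, i : j + 1] = True
                else:
                    test(i + 1, j)
                    test(i, j - 1)

            test(0, k - 1)

    # compact letter display from maximal non-significant spans
    spans = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        spans.append((i, j))
    maximal = [s for s in spans if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in spans)]
    letters = ["" for _ in range(k)]
    for letter_idx, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for t in range(i, j + 1):
            letters[t] += ch

    out = pd.DataFrame({
        "group": [names[i] for i in order],
        "n": ns[order],
        "mean": sorted_means,
        "letters": letters,
    }).set_index("group")
    return out


# ---------------------------------------------------------------------------
# Window scans


@dataclass
class WindowTrack:
    """Per-(chrom, window) group-mean [AT]; value NaN when n_sites < min_sites."""

    df: pd.DataFrame  # chrom, start, end, n_sites, at_value (group mean)
    group: str = ""


def make_windows(lengths: dict[str, int], window: int, step: int) -> pd.DataFrame:
    rows = []
    for chrom, length in lengths.items():
        start = 1
        while start <= length:
            rows.append({"chrom": chrom, "start": start, "end": min(start + window - 1, length)})
            start += step
    return pd.DataFrame(rows)


def window_at(geno: GenotypeMatrix, panel: AccessionPanel, groups: list[str],
              lengths: dict[str, int], window: int = 2_000_000,
              step: int = 1_000_000, min_sites: int = 10) -> dict[str, WindowTrack]:
    """Sliding-window group-mean [AT] per group.

    Windows with fewer than ``min_sites`` SNPs are flagged missing (NaN).
    Trailing partial windows are kept subject to the same site minimum.
    """
    wins = make_windows(lengths, window, step)
    sdf = geno.sites.df
    tracks = {}
    group_idx = {g: geno.accession_index([a for a in panel.members(g) if a in geno.accessions])
                 for g in groups}
    for g in groups:
        if len(group_idx[g]) == 0:
            raise ValueError(f"group {g!r} has no accessions in the genotype matrix")
    pos_by_chrom = {c: (sub.index.to_numpy(), sub["pos"].to_numpy())
                    for c, sub in sdf.groupby("chrom")}
    records = {g: [] for g in groups}
    for _, w in wins.iterrows():
        if w.chrom in pos_by_chrom:
            idx_all, pos = pos_by_chrom[w.chrom]
            lo, hi = np.searchsorted(pos, [w.start, w.end + 1])
            site_idx = idx_all[lo:hi]
        else:
            site_idx = np.array([], dtype=int)
        for g in groups:
            if len(site_idx) < min_sites:
                val = np.nan
            else:
                sums, n_used = base_sums(geno, site_idx)
                sums, n_used = sums[group_idx[g]], n_used[group_idx[g]]
                with np.errstate(invalid="ignore", divide="ignore"):
                    at = (sums[:, 0] + sums[:, 3]) / n_used
                val = float(np.nanmean(at))
            records[g].append({"chrom": w.chrom, "start": int(w.start), "end": int(w.end),
                               "n_sites": len(site_idx), "at_value": val})
    return {g: WindowTrack(pd.DataFrame(records[g]), g) for g in groups}


def window_difference(track_dom: WindowTrack, track_wild: WindowTrack,
                      boundary: float = 0.1) -> tuple[pd.DataFrame, dict]:
    """Per-window [AT] difference (domesticated - wild, absolute fractions).

    Also reports the fraction of comparable windows with delta > 0 and with
    delta > ``boundary``, and a relative (percent-change) delta column since
    per-chromosome increases are sometimes quoted on that scale.
    """
    a, b = track_dom.df, track_wild.df
    if not (a[["chrom", "start", "end"]].values == b[["chrom", "start", "end"]].values).all():
        raise ValueError("window tracks do not share the same windows")
    out = a[["chrom", "start", "end", "n_sites"]].copy()
    out["at_dom"] = a["at_value"]
    out["at_wild"] = b["at_value"]
    out["delta_at"] = a["at_value"] - b["at_value"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["delta_at_rel"] = out["delta_at"] / b["at_value"]
    ok = out["delta_at"].notna()
    if not ok.any():
        raise ValueError("no windows comparable between the two tracks")
    summary = {
        "n_windows": int(ok.sum()),
        "frac_positive": float((out.loc[ok, "delta_at"] > 0).mean()),
        "frac_above_boundary": float((out.loc[ok, "delta_at"] > boundary).mean()),
    }
    return out, summary


# ---------------------------------------------------------------------------
# Region stratification


def stratified_at(geno: GenotypeMatrix, panel: AccessionPanel, regions: RegionSet,
                  mode: str = "inside_vs_outside", min_sites: int = 10,
                  ) -> dict[str, CompositionProfile]:
    """Accession composition restricted to region strata.

    ``inside_vs_outside`` yields two strata ("inside", "outside"); ``per_region``
    one per region label plus "outside".  Strata with fewer than ``min_sites``
    SNPs are skipped with a log message.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    sdf = geno.sites.df
    inside = regions.contains(sdf["chrom"].to_numpy(), sdf["pos"].to_numpy())
    strata: dict[str, np.ndarray] = {}
    if mode == "inside_vs_outside":
        strata["inside"] = np.flatnonzero(inside)
        strata["outside"] = np.flatnonzero(~inside)
    elif mode == "per_region":
        for label, sub in regions.df.groupby("label", sort=False):
            m = RegionSet(sub).contains(sdf["chrom"].to_numpy(), sdf["pos"].to_numpy())
            strata[str(label)] = np.flatnonzero(m)
        strata["outside"] = np.flatnonzero(~inside)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for name, idx in strata.items():
        if len(idx) < min_sites:
            log.info("stratified_at: stratum %r has %d sites (< %d), skipped",
                     name, len(idx), min_sites)
            continue
        out[name] = accession_composition(geno, idx, scope=name)
    return out
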