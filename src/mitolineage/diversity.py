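"""Summary statistics of mitogenome variation: S, Hd, pi, k, Tajima's D.

Statistics are computed from variant profiles, not raw alignments.  The
default site policy is the one classical diversity software applies to
sequence data: complete deletion (a position with an ambiguous base in any
sample is dropped for everyone) and substitutions only (indels do not count
as sites); both are toggles.  Hotspot/poly-C masking is deliberately NOT
applied here by default — the exclusion list belongs to dating and tree
building, while diversity indices use the full genome — but callers can
mask profiles first if desired.

Tajima's D significance is assessed by neutral coalescent simulation
conditional on the observed number of segregating sites rather than by the
beta approximation; the replicate count and seed are explicit arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import HaplotypeClass, collapse_haplotypes
from .refio import RCRS_LENGTH, VariantProfile


class DiversityError(ValueError):
    pass


@dataclass
class DiversitySummary:
    population: str
    n: int
    h: int
    S: int
    Hd: float
    Hd_SD: float
    Pi: float
    Pi_SD: float
    k: float
    D: float
    D_significance: str


# ---------------------------------------------------------------------------
# site bookkeeping


def _usable_positions(profiles: Sequence[VariantProfile],
                      complete_deletion: bool = True) -> set[int]:
    """Reference positions excluded by the deletion policy (ambiguity in any
    sample under complete deletion)."""
    if not complete_deletion:
        return set()
    excluded: set[int] = set()
    for p in profiles:
        excluded |= set(p.uncompared)
    return excluded


def _site_states(profiles: Sequence[VariantProfile], include_indels: bool,
                 complete_deletion: bool = True) -> dict[tuple, list[str]]:
    """Observed state per sample at every varying site.

    Substitution sites are keyed (position, 0, "sub") with "." for the
    reference state; indel sites (when included) are keyed per slot.
    """
    excluded = _usable_positions(profiles, complete_deletion)
    sites: dict[tuple, dict[int, str]] = {}
    for i, p in enumerate(profiles):
        for v in p.variants:
            if v.position in excluded:
                continue
            if v.is_indel:
                if not include_indels:
                    continue
                key = (v.position, v.insert_index, "indel")
                sites.setdefault(key, {})[i] = v.label
            else:
                key = (v.position, 0, "sub")
                sites.setdefault(key, {})[i] = v.derived_state
    out: dict[tuple, list[str]] = {}
    for key, carriers in sites.items():
        pos = key[0]
        states = []
        for i, p in enumerate(profiles):
            if not complete_deletion and pos in p.uncompared:
                states.append("?")
            else:
                states.append(carriers.get(i, "."))
        out[key] = states
    return out


def segregating_sites(profiles: Sequence[VariantProfile],
                      include_indels: bool = False,
                      complete_deletion: bool = True) -> int:
    """Number of sites with at least two observed states."""
    if not profiles:
        raise DiversityError("no profiles")
    sites = _site_states(profiles, include_indels, complete_deletion)
    S = 0
    for states in sites.values():
        observed = {s for s in states if s != "?"}
        if len(observed) >= 2:
            S += 1
    return S


def haplotype_diversity(classes: Sequence[HaplotypeClass]) -> tuple[float, float]:
    """Nei's haplotype diversity (unbiased) and its sampling SD."""
    n = sum(c.multiplicity for c in classes)
    if n < 2:
        raise DiversityError("haplotype diversity needs n >= 2")
    p = np.array([c.multiplicity / n for c in classes])
    sum2 = float(np.sum(p ** 2))
    sum3 = float(np.sum(p ** 3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    return hd, math.sqrt(max(0.0, var))


def pairwise_stats(profiles: Sequence[VariantProfile],
                   include_indels: bool = False,
                   complete_deletion: bool = True,
                   genome_length: int = RCRS_LENGTH) -> tuple[float, float, float]:
    """Mean pairwise differences k, per-site diversity pi, and pi's SD.

    Under complete deletion every pair is compared at the same site set, so
    k can be accumulated per segregating site; under pairwise deletion each
    pair is compared at its own mutually resolved sites.
    """
    n = len(profiles)
    if n < 2:
        raise DiversityError("pairwise statistics need n >= 2")
    n_pairs = n * (n - 1) / 2
    if complete_deletion:
        excluded = _usable_positions(profiles, True)
        compared_sites = genome_length - len(excluded)
        if compared_sites <= 0:
            raise DiversityError("no compared sites under complete deletion")
        sites = _site_states(profiles, include_indels, True)
        diff_total = 0.0
        for states in sites.values():
            counts: dict[str, int] = {}
            for s in states:
                counts[s] = counts.get(s, 0) + 1
            same = sum(c * (c - 1) / 2 for c in counts.values())
            diff_total += n_pairs - same
        k = diff_total / n_pairs
        pi = k / compared_sites
    else:
        total_k = 0.0
        total_pi = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                shared_excl = set(profiles[i].uncompared) | set(profiles[j].uncompared)
                sites_ij = genome_length - len(shared_excl)
                di = {(v.position, v.insert_index): v.label
                      for v in profiles[i].variants
                      if (include_indels or not v.is_indel)
                      and v.position not in shared_excl}
                dj = {(v.position, v.insert_index): v.label
                      for v in profiles[j].variants
                      if (include_indels or not v.is_indel)
                      and v.position not in shared_excl}
                diffs = sum(1 for slot in set(di) | set(dj)
                            if di.get(slot) != dj.get(slot))
                total_k += diffs
                total_pi += diffs / sites_ij
        k = total_k / n_pairs
        pi = total_pi / n_pairs
        compared_sites = genome_length
    # Tajima's total variance of the per-site estimate
    var = ((n + 1) / (3.0 * (n - 1)) * pi / compared_sites
           + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1)) * pi ** 2)
    return k, pi, math.sqrt(max(0.0, var))


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, k: float, n: int,
              n_reps: int = 0, seed: int = 0) -> tuple[float, str]:
    """Tajima's D and (optionally) its simulation-based significance class.

    D contrasts the mean pairwise difference k with the segregating-site
    estimator S/a1.  With ``n_reps`` > 0, a two-tailed empirical p-value is
    obtained from neutral constant-size coalescent replicates conditioned on
    S segregating sites, and binned at the 0.05 / 0.01 / 0.001 levels.
    """
    if n < 4:
        raise DiversityError("Tajima's D needs n >= 4")
    if S < 1:
        raise DiversityError("Tajima's D undefined at S = 0")
    c = _tajima_constants(n)
    D = (k - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    if n_reps <= 0:
        return D, "n.d."
    sims = simulate_tajimas_d_null(n, S, n_reps, seed)
    lo = float(np.mean(sims <= D))
    hi = float(np.mean(sims >= D))
    p = min(1.0, 2.0 * min(lo, hi))
    if p < 0.001:
        sig = "P<0.001"
    elif p < 0.01:
        sig = "P<0.01"
    elif p < 0.05:
        sig = "P<0.05"
    else:
        sig = "ns"
    return D, sig


def simulate_tajimas_d_null(n: int, S: int, n_reps: int,
                            seed: int) -> np.ndarray:
    """Null distribution of D for n samples conditioned on S sites.

    Each replicate draws a neutral constant-size Kingman genealogy and
    scatters the S segregating sites onto branches with probability
    proportional to branch length (the fixed-S approach).
    """
    rng = np.random.default_rng(seed)
    c = _tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    out = np.empty(n_reps)
    for r in range(n_reps):
        counts, lengths = _kingman_branches(n, rng)
        probs = lengths / lengths.sum()
        hits = rng.multinomial(S, probs)
        d = counts[hits > 0]
        h = hits[hits > 0]
        k_hat = float(np.sum(h * 2.0 * d * (n - d)) / (n * (n - 1)))
        out[r] = (k_hat - S / c["a1"]) / denom
    return out


def _kingman_branches(n: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Descendant count and branch length for every branch of one neutral
    coalescent genealogy (time in coalescent units; only ratios matter)."""
    desc = list(np.ones(n))
    birth = list(np.zeros(n))
    t = 0.0
    counts, lengths = [], []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        for idx in sorted((i, j), reverse=True):
            counts.append(desc[idx])
            lengths.append(t - birth[idx])
        merged = desc[i] + desc[j]
        for idx in sorted((i, j), reverse=True):
            del desc[idx], birth[idx]
        desc.append(merged)
        birth.append(t)
        k -= 1
    return np.array(counts, dtype=float), np.array(lengths, dtype=float)


# ---------------------------------------------------------------------------
# per-population summary


def summarize(profiles: Sequence[VariantProfile], metadata: pd.DataFrame,
              include_indels_in_sites: bool = False,
              include_indels_in_haplotypes: bool = True,
              complete_deletion: bool = True,
              d_significance_reps: int = 2000,
              seed: int = 0) -> pd.DataFrame:
    """One diversity row per population plus a combined Total row.

    Haplotype counts default to complete profiles (substitutions + indels)
    while site statistics default to substitutions only; both are toggles.
    """
    meta = metadata.set_index("sample_id")["population"]
    by_pop: dict[str, list[VariantProfile]] = {}
    for p in profiles:
        if p.sample_id not in meta.index:
            raise DiversityError(f"sample {p.sample_id!r} missing from metadata")
        by_pop.setdefault(str(meta.loc[p.sample_id]), []).append(p)
    rows = []
    groups = [("Total", list(profiles))] + sorted(by_pop.items())
    for pop, group in groups:
        if len(group) < 2:
            warnings.warn(f"population {pop!r} has n < 2; skipped")
            continue
        rows.append(_summary_row(pop, group, include_indels_in_sites,
                                 include_indels_in_haplotypes,
                                 complete_deletion, d_significance_reps, seed))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df


def _summary_row(pop: str, group: Sequence[VariantProfile],
                 include_indels_in_sites: bool,
                 include_indels_in_haplotypes: bool,
                 complete_deletion: bool,
                 d_reps: int, seed: int) -> DiversitySummary:
    n = len(group)
    if include_indels_in_haplotypes:
        classes = collapse_haplotypes(group)
    else:
        subs_only = [VariantProfile(sample_id=p.sample_id,
                                    variants=p.substitutions(),
                                    uncompared=p.uncompared) for p in group]
        classes = collapse_haplotypes(subs_only)
    S = segregating_sites(group, include_indels_in_sites, complete_deletion)
    hd, hd_sd = haplotype_diversity(classes)
    k, pi, pi_sd = pairwise_stats(group, include_indels_in_sites,
                                  complete_deletion)
    if n >= 4 and S >= 1:
        D, sig = tajimas_d(S, k, n, n_reps=d_reps, seed=seed)
    else:
        D, sig = float("nan"), "n.d."
    return DiversitySummary(population=pop, n=n, h=len(classes), S=S,
                            Hd=hd, Hd_SD=hd_sd, Pi=pi, Pi_SD=pi_sd,
                            k=k, D=D, D_significance=sig)
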