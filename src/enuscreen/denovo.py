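"""Trio-based de novo mutation detection and mutation-frequency estimation.

An explicit Bayesian trio model stands behind the screen's calling criteria:
per-genotype binomial read likelihoods, Hardy-Weinberg parental priors, and
Mendelian transmission with a small per-gamete mutation prior mu.  A candidate
site is called de novo when the posterior probability of a configuration that
*requires* a mutation event (pp_dnm) exceeds 0.9 while the posterior of a
Mendelian configuration with a non-reference child (pp_null) stays below 0.001,
every trio member is covered by at least 10 reads, and the same site is not
called in more than one trio (independent sperm carry disjoint mutation sets).

The pooled per-site mutation frequency is the call count divided by the pooled
callable sites, with an exact Poisson 95% interval on the count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ReadCountSet

__all__ = [
    "TrioPriors",
    "DenovoCall",
    "FrequencyEstimate",
    "genotype_likelihoods",
    "trio_posteriors",
    "call_denovo",
    "estimate_frequency",
    "TrioDenovoModel",
    "TrioDenovoResults",
]

P_ALT_BY_GENOTYPE = ("epsilon", 0.5, "1-epsilon")  # documentation constant


@dataclass(frozen=True)
class TrioPriors:
    """Model priors: per-gamete de novo rate ``mu``, background polymorphism
    allele frequency ``pop_alt_freq`` (one value for all sites), and per-read
    error ``epsilon``.

    ``mu`` defaults to the mutagenized regime the caller targets (ENU dose
    calibrations run 1.6e-6 to 5.9e-6 per site per gamete).  ``pop_alt_freq``
    is the HWE prior that a random — overwhelmingly monomorphic, and not
    already catalogued — site segregates in the founders; it is set an order
    of magnitude below the induced-mutation prior so that the Mendelian
    explanation competes through the parental read likelihoods rather than
    through the prior (a parent with a stray error read would otherwise push
    pp_null past the 0.001 criterion at ordinary 20x coverage).  Known common
    variation is the province of the catalogued-SNP exclusion downstream.
    Both are configurable.
    """

    mu: float = 5e-6
    pop_alt_freq: float = 1e-6
    epsilon: float = 0.01

    def __post_init__(self):
        for name in ("mu", "pop_alt_freq", "epsilon"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclass(frozen=True)
class DenovoCall:
    chromosome: str
    position: int
    child_id: str
    trio_index: int
    pp_dnm: float
    pp_null: float
    depths: tuple[int, int, int]  # father, mother, child
    passed_filters: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class FrequencyEstimate:
    n_mutations: int
    callable_sites: int
    rate: float
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# likelihoods and posteriors


def genotype_likelihoods(
    ref_count: int, alt_count: int, epsilon: float = 0.01
) -> tuple[float, float, float]:
    """Binomial likelihoods of (hom-ref, het, hom-alt) given read counts.

    Depth 0 returns the flat uninformative triple (1, 1, 1).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    depth = ref_count + alt_count
    if depth == 0:
        return (1.0, 1.0, 1.0)
    p = np.array([epsilon, 0.5, 1.0 - epsilon])
    lik = stats.binom.pmf(alt_count, depth, p)
    return (float(lik[0]), float(lik[1]), float(lik[2]))


def _transmission_tensor(mu: float) -> np.ndarray:
    """P(child genotype | father, mother) with per-gamete mutation rate mu.

    A gamete transmits a Mendelian allele with probability 1 - mu and the
    mutated alternative with probability mu; shape (3, 3, 3) = (gf, gm, gc).
    """
    g = np.arange(3)
    p_alt = (g / 2.0) * (1 - mu) + (1 - g / 2.0) * mu  # P(gamete carries alt | g)
    T = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = p_alt[gf], p_alt[gm]
            T[gf, gm, 0] = (1 - pf) * (1 - pm)
            T[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            T[gf, gm, 2] = pf * pm
    return T


def _mendelian_possible() -> np.ndarray:
    """Boolean (gf, gm, gc): child genotype achievable without any mutation."""
    allowed = {0: {0}, 1: {0, 1}, 2: {1}}  # transmissible allele counts
    M = np.zeros((3, 3, 3), dtype=bool)
    for gf in range(3):
        for gm in range(3):
            for a in allowed[gf]:
                for b in allowed[gm]:
                    M[gf, gm, a + b] = True
    return M


def _hwe(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def trio_posteriors(
    father: tuple[float, float, float],
    mother: tuple[float, float, float],
    child: tuple[float, float, float],
    priors: TrioPriors = TrioPriors(),
) -> tuple[float, float]:
    """(pp_dnm, pp_null) from the 27 trio genotype configurations.

    pp_dnm is the posterior mass of configurations whose child genotype cannot
    arise from Mendelian transmission of the parental genotypes; pp_null is the
    mass of Mendelian-achievable configurations in which the child carries at
    least one alternative allele.
    """
    T = _transmission_tensor(priors.mu)
    M = _mendelian_possible()
    hwe = _hwe(priors.pop_alt_freq)
    Lf = np.asarray(father)
    Lm = np.asarray(mother)
    Lc = np.asarray(child)
    joint = (
        (hwe * Lf)[:, None, None] * (hwe * Lm)[None, :, None] * T * Lc[None, None, :]
    )
    total = joint.sum()
    if total == 0:
        return (0.0, 0.0)
    dnm = joint[~M].sum()
    child_alt = np.zeros((3, 3, 3), dtype=bool)
    child_alt[:, :, 1:] = True
    null = joint[M & child_alt].sum()
    return (float(dnm / total), float(null / total))


def _vector_posteriors(
    counts: list[tuple[np.ndarray, np.ndarray]], priors: TrioPriors
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (pp_dnm, pp_null) for arrays of (ref, alt) counts of
    father, mother, child."""
    T = _transmission_tensor(priors.mu)
    M = _mendelian_possible()
    hwe = _hwe(priors.pop_alt_freq)
    p_geno = np.array([priors.epsilon, 0.5, 1.0 - priors.epsilon])

    liks = []
    for ref, alt in counts:
        depth = ref.astype(np.int64) + alt
        L = stats.binom.pmf(alt[:, None], depth[:, None], p_geno[None, :])
        L[depth == 0] = 1.0  # uninformative
        liks.append(L)
    Lf, Lm, Lc = liks

    n = len(Lf)
    total = np.zeros(n)
    dnm = np.zeros(n)
    null = np.zeros(n)
    for gf in range(3):
        for gm in range(3):
            parent_w = hwe[gf] * hwe[gm] * Lf[:, gf] * Lm[:, gm]
            for gc in range(3):
                w = parent_w * T[gf, gm, gc] * Lc[:, gc]
                total += w
                if not M[gf, gm, gc]:
                    dnm += w
                elif gc >= 1:
                    null += w
    with np.errstate(invalid="ignore", divide="ignore"):
        pp_dnm = np.where(total > 0, dnm / total, 0.0)
        pp_null = np.where(total > 0, null / total, 0.0)
    return pp_dnm, pp_null


# ---------------------------------------------------------------------------
# calling


def call_denovo(
    counts: ReadCountSet,
    trios: list[tuple[str, str, str]],
    priors: TrioPriors = TrioPriors(),
    pp_dnm_min: float = 0.9,
    pp_null_max: float = 0.001,
    min_depth: int = 10,
    depth_rule: str = "all",
    cross_trio_exclusion: bool = True,
) -> tuple[list[DenovoCall], dict[int, int]]:
    """Call de novo mutations in each (child, father, mother) trio.

    A site is callable for a trio when the depth rule holds (``all``: every
    member covered by >= min_depth reads — the stringent reading; ``any``: at
    least one member).  A call passes when the site is callable, pp_dnm >
    pp_dnm_min and pp_null < pp_null_max (strict inequalities, thresholds as
    printed).  With cross-trio exclusion, passing calls at the same site in
    more than one trio are all removed.

    Returns the calls and a per-trio callable-site count.
    """
    if depth_rule not in ("all", "any"):
        raise ValueError("depth_rule must be 'all' or 'any'")
    calls: list[DenovoCall] = []
    callable_sites: dict[int, int] = {}
    site_hits: dict[tuple[int, int], list[int]] = {}

    for t_idx, (child, father, mother) in enumerate(trios):
        for ind in (child, father, mother):
            if ind not in counts.counts:
                raise KeyError(f"no read counts for {ind}")
        df = counts.depth(father)
        dm = counts.depth(mother)
        dc = counts.depth(child)
        if depth_rule == "all":
            callable_mask = (df >= min_depth) & (dm >= min_depth) & (dc >= min_depth)
        else:
            callable_mask = (df >= min_depth) | (dm >= min_depth) | (dc >= min_depth)
        callable_sites[t_idx] = int(callable_mask.sum())

        # only sites with alt evidence in the child can reach pp_dnm > 0.9
        cand = np.flatnonzero(callable_mask & (counts.counts[child][1] > 0))
        if len(cand) == 0:
            continue
        sub = [
            (counts.counts[ind][0][cand], counts.counts[ind][1][cand])
            for ind in (father, mother, child)
        ]
        pp_dnm, pp_null = _vector_posteriors(sub, priors)
        passing = np.flatnonzero((pp_dnm > pp_dnm_min) & (pp_null < pp_null_max))
        for k in passing:
            i = int(cand[k])
            call = DenovoCall(
                counts.chrom_names[counts.chrom[i]],
                int(counts.pos[i]),
                child,
                t_idx,
                float(pp_dnm[k]),
                float(pp_null[k]),
                (int(df[i]), int(dm[i]), int(dc[i])),
                passed_filters={
                    "pp_dnm": True,
                    "pp_null": True,
                    "depth": True,
                    "single_trio": True,
                },
            )
            calls.append(call)
            site_hits.setdefault((int(counts.chrom[i]), int(counts.pos[i])), []).append(
                len(calls) - 1
            )

    if cross_trio_exclusion:
        drop = set()
        for site, idxs in site_hits.items():
            if len({calls[i].trio_index for i in idxs}) > 1:
                for i in idxs:
                    calls[i].passed_filters["single_trio"] = False
                    drop.add(i)
        calls = [c for i, c in enumerate(calls) if i not in drop]
    return calls, callable_sites


def estimate_frequency(
    calls: list[DenovoCall] | int, callable_sites: dict[int, int] | int
) -> FrequencyEstimate:
    """Pooled per-site mutation frequency with an exact Poisson 95% CI.

    ``calls`` may be a call list or a plain count; ``callable_sites`` a per-trio
    mapping (pooled by summation) or a plain total.
    """
    n = calls if isinstance(calls, int) else len(calls)
    total = (
        callable_sites if isinstance(callable_sites, int) else sum(callable_sites.values())
    )
    if total <= 0:
        raise ValueError("callable_sites must be positive")
    lo = 0.0 if n == 0 else stats.chi2.ppf(0.025, 2 * n) / 2.0
    hi = stats.chi2.ppf(0.975, 2 * (n + 1)) / 2.0
    return FrequencyEstimate(n, total, n / total, (lo / total, hi / total))


# ---------------------------------------------------------------------------
# model/results presentation


class TrioDenovoModel:
    """Trio de novo calling as a fitted model.

    Parameters
    ----------
    counts
        Shared-site read counts for all trio members.
    trios
        ``(child, father, mother)`` id triples.
    priors
        :class:`TrioPriors`; defaults follow the package's generative model.
    """

    def __init__(
        self,
        counts: ReadCountSet,
        trios: list[tuple[str, str, str]],
        priors: TrioPriors = TrioPriors(),
    ):
        self.counts = counts
        self.trios = list(trios)
        self.priors = priors

    def fit(
        self,
        pp_dnm_min: float = 0.9,
        pp_null_max: float = 0.001,
        min_depth: int = 10,
        depth_rule: str = "all",
        cross_trio_exclusion: bool = True,
    ) -> "TrioDenovoResults":
        calls, callable_sites = call_denovo(
            self.counts,
            self.trios,
            self.priors,
            pp_dnm_min=pp_dnm_min,
            pp_null_max=pp_null_max,
            min_depth=min_depth,
            depth_rule=depth_rule,
            cross_trio_exclusion=cross_trio_exclusion,
        )
        freq = estimate_frequency(calls, callable_sites)
        return TrioDenovoResults(self, calls, callable_sites, freq)


class TrioDenovoResults:
    """Calls, per-trio callable-site counts and the pooled frequency estimate."""

    def __init__(self, model, calls, callable_sites, frequency):
        self.model = model
        self.calls: list[DenovoCall] = calls
        self.callable_sites: dict[int, int] = callable_sites
        self.frequency: FrequencyEstimate = frequency

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": c.chromosome,
                    "pos": c.position,
                    "child": c.child_id,
                    "trio": c.trio_index,
                    "pp_dnm": c.pp_dnm,
                    "pp_null": c.pp_null,
                    "depth_father": c.depths[0],
                    "depth_mother": c.depths[1],
                    "depth_child": c.depths[2],
                }
            for c in self.calls],
            columns=[
                "chrom", "pos", "child", "trio", "pp_dnm", "pp_null",
                "depth_father", "depth_mother", "depth_child",
            ],
        )

    def summary(self) -> str:
        f = self.frequency
        lines = [
            "Trio de novo mutation calling",
            "=" * 45,
            f"trios:               {len(self.model.trios)}",
            f"de novo calls:       {f.n_mutations}",
            f"pooled callable:     {f.callable_sites}",
            f"rate (per site):     {f.rate:.3e}",
            f"95% CI:              ({f.ci95[0]:.3e}, {f.ci95[1]:.3e})",
        ]
        for t, n in sorted(self.callable_sites.items()):
            child = self.model.trios[t][0]
            k = sum(c.trio_index == t for c in self.calls)
            lines.append(f"  trio {t} ({child}): {k} calls / {n} callable")
        return "\n".join(lines)
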