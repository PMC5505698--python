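"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by direct enumeration or simulation, on a
path disjoint from the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from enuscreen.linkage import (
    DISEASE_GENO,
    MARKER_GENO,
    DiseaseModel,
    _founder_prior,
    _transmission,
)


def trio_posterior_oracle(lf, lm, lc, mu, q):
    """(pp_dnm, pp_null) by explicit enumeration of the 27 trio genotype
    configurations with HWE parental priors and mutation-aware transmission."""

    def hwe(g):
        return [(1 - q) ** 2, 2 * q * (1 - q), q**2][g]

    def p_alt(g):
        return (g / 2) * (1 - mu) + (1 - g / 2) * mu

    allowed = {0: {0}, 1: {0, 1}, 2: {1}}
    total = dnm = null = 0.0
    for gf in (0, 1, 2):
        for gm in (0, 1, 2):
            pf, pm = p_alt(gf), p_alt(gm)
            trans = {
                0: (1 - pf) * (1 - pm),
                1: pf * (1 - pm) + (1 - pf) * pm,
                2: pf * pm,
            }
            for gc in (0, 1, 2):
                w = hwe(gf) * hwe(gm) * trans[gc] * lf[gf] * lm[gm] * lc[gc]
                total += w
                mendelian = any(a + b == gc for a in allowed[gf] for b in allowed[gm])
                if not mendelian:
                    dnm += w
                elif gc >= 1:
                    null += w
    if total == 0:
        return 0.0, 0.0
    return dnm / total, null / total


def pedigree_likelihood_oracle(ped, genotypes, alt_freq, disease_model: DiseaseModel,
                               thetas):
    """Exact two-locus pedigree likelihood by materializing the full joint over
    one 16-state axis per individual (feasible up to ~6 individuals)."""
    ids = list(ped.individuals)
    n = len(ids)
    if n > 6:
        raise ValueError("oracle limited to 6 individuals (16^n joint)")
    idx = {i: k for k, i in enumerate(ids)}
    Tr = _transmission(np.asarray(thetas, float))
    F = _founder_prior(np.array([alt_freq]), disease_model.q)[0]
    pen = np.asarray(disease_model.penetrances)
    out = []
    for t in range(len(thetas)):
        joint = np.ones((16,) * n)
        for i, ind in enumerate(ped):
            vec = np.ones(16)
            g = genotypes.get(ind.id, -1)
            if g is not None and g >= 0:
                vec = vec * (MARKER_GENO == g)
            if ind.affected is True:
                vec = vec * pen[DISEASE_GENO]
            elif ind.affected is False:
                vec = vec * (1 - pen[DISEASE_GENO])
            if ind.is_founder:
                vec = vec * F
            shape = [1] * n
            shape[i] = 16
            joint = joint * vec.reshape(shape)
            if not ind.is_founder:
                ks, kd = idx[ind.sire_id], idx[ind.dam_id]
                T3 = np.zeros((16, 16, 16))  # (sire, dam, child)
                for s in range(16):
                    T3[:, :, s] = np.outer(Tr[t, :, s // 4], Tr[t, :, s % 4])
                shape = [16 if d in (ks, kd, i) else 1 for d in range(n)]
                order = np.argsort([ks, kd, i])
                joint = joint * np.transpose(T3, order).reshape(shape)
        out.append(joint.sum())
    return np.array(out)


def recessive_power_mc(n_dams, offspring, penetrance, n_rep=100_000, seed=0):
    """Monte-Carlo detection probability of the backcross design."""
    rng = np.random.default_rng(seed)
    carrier = rng.random((n_rep, n_dams)) < 0.5
    affected = rng.binomial(offspring, penetrance / 4.0, size=(n_rep, n_dams))
    return float(((carrier) & (affected > 0)).any(axis=1).mean())
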