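"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editscape import Condition, EditingProfile, SimConfig, simulate_editing_profile


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementations they check)


def wilcoxon_enumeration_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(x)
    obs = ranks[:n1].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
    p_ge = np.mean(sums >= obs - 1e-9)
    p_le = np.mean(sums <= obs + 1e-9)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def hypergeom_enumeration_oracle(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) by direct summation of the hypergeometric pmf."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def seed_scan_oracle(mirna: str, utr: str) -> set[tuple[int, str]]:
    """Brute-force canonical seed-site scan by direct substring matching.

    Returns {(1-based start, site_type)} after 8mer dominance: a 7mer-m8
    at the same start as an 8mer, or a 7mer-A1 one base downstream of an
    8mer start, is subsumed by the 8mer.
    """
    rc = {"A": "U", "U": "A", "C": "G", "G": "C"}
    m = mirna.upper().replace("T", "U")
    u = utr.upper().replace("T", "U")
    m2_8 = "".join(rc[c] for c in reversed(m[1:8]))
    m2_7 = "".join(rc[c] for c in reversed(m[1:7]))
    patterns = {"8mer": m2_8 + "A", "7mer-m8": m2_8, "7mer-A1": m2_7 + "A"}
    raw: set[tuple[int, str]] = set()
    for typ, pat in patterns.items():
        for s in range(len(u) - len(pat) + 1):
            if u[s : s + len(pat)] == pat:
                raw.add((s + 1, typ))
    eights = {s for s, t in raw if t == "8mer"}
    return {
        (s, t)
        for s, t in raw
        if t == "8mer"
        or (t == "7mer-m8" and s not in eights)
        or (t == "7mer-A1" and s - 1 not in eights)
    }


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with planted DESs (deterministic)."""
    cfg = SimConfig(n_sites=400, n_resistant=20, n_sensitive=20, seed=42)
    profile, response, truth = simulate_editing_profile(cfg)
    return cfg, profile, response, truth


@pytest.fixture(scope="session")
def small_condition(small_sim):
    _, profile, _, _ = small_sim
    samples = profile.sample_ids
    res = frozenset(s for s in samples if s.startswith("R"))
    sen = frozenset(s for s in samples if s.startswith("S"))
    return Condition("CancerA", "DrugA", res, sen)


@pytest.fixture()
def tiny_profile():
    """2 sites x 2 samples with one missing entry."""
    levels = pd.DataFrame(
        {"s1": [0.2, 0.4], "s2": [np.nan, 0.6]},
        index=pd.Index(["siteA", "siteB"], name="site_id"),
    )
    return EditingProfile(levels)
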