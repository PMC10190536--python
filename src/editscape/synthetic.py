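"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of bulk tumor editing
profiles: per-site editing levels follow a beta law on [0, 1] with
missing-at-random dropout, a configurable fraction of sites carry a
planted resistant-vs-sensitive mean shift (the ground-truth DESs),
ADAR-like expression is linearly coupled to the per-sample overall
editing level with an analytically chosen noise variance so a target
R^2 is recoverable, survival times follow exponential hazards with a
planted hazard ratio between editing groups, and 3'-UTR sequences carry
plantable miRNA seed-site gains and losses under A->G editing.

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    REGIONS,
    RESISTANT_LABEL,
    SENSITIVE_LABEL,
    EditingProfile,
)
from .mirna import find_seed_sites, reverse_complement, seed_match_strings, to_rna

log = logging.getLogger(__name__)

#: Default share of sites per transcribed region. Editing concentrates in
#: intronic sequence and 3'-UTRs (where double-stranded structure forms),
#: with coding regions carrying only a small fraction.
DEFAULT_REGION_PROPORTIONS = {
    "3'-UTR": 0.30,
    "5'-UTR": 0.05,
    "exonic": 0.05,
    "intronic": 0.45,
    "intergenic": 0.10,
    "ncRNA": 0.05,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated (cancer, drug) condition.

    Defaults describe a mid-sized bulk cohort: 2000 editing sites,
    20 resistant and 20 sensitive samples, 10% missing measurements,
    5% of sites carrying a 15-percentage-point editing shift, half of
    them over-edited in resistant samples, a baseline editing level of
    0.25, ADAR expression explaining 11% of OEL variance, and a planted
    hazard ratio of 2 with 30% censoring.
    """

    n_sites: int = 2000
    n_resistant: int = 20
    n_sensitive: int = 20
    missing_rate: float = 0.10
    des_fraction: float = 0.05
    effect_size: float = 0.15
    over_editing_proportion: float = 0.5
    beta_mean: float = 0.25
    beta_concentration: float = 20.0
    region_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROPORTIONS)
    )
    adar_r2_target: float = 0.11
    survival_hr: float = 2.0
    censoring_rate: float = 0.30
    n_genes: int = 200
    cancer: str = "CancerA"
    drug: str = "DrugA"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "des_fraction", "over_editing_proportion",
                     "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_sites", "n_resistant", "n_sensitive", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.beta_mean < 1:
            raise ValueError("beta_mean must be in (0, 1)")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        if not 0 <= self.adar_r2_target < 1:
            raise ValueError("adar_r2_target must be in [0, 1)")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be positive")
        total = sum(self.region_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region_proportions must sum to 1, got {total}")
        unknown = set(self.region_proportions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
        if self.des_fraction > 0 and not (
            0 < self.beta_mean - self.effect_size
            and self.beta_mean + self.effect_size < 1
        ):
            raise ValueError(
                f"effect size {self.effect_size} incompatible with beta support: "
                f"baseline mean {self.beta_mean} +/- effect must stay inside (0, 1)"
            )


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset.

    ``sites`` is indexed by site id with columns is_des, planted_diff,
    region, gene_id, chrom, pos, strand. ``triplets`` lists planted
    (site_id, mirna_id, gene_id, kind) rewiring events.
    """

    sites: pd.DataFrame
    triplets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["site_id", "mirna_id", "gene_id", "kind"]
        )
    )


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


# ---------------------------------------------------------------------------
# editing profile


def simulate_editing_profile(
    config: SimConfig,
) -> tuple[EditingProfile, pd.DataFrame, TruthTable]:
    """Generate an editing matrix, a drug-response table and the truth.

    Sensitive samples draw every site from Beta with the baseline mean;
    at planted DESs the resistant group's beta mean is shifted by the
    signed planted diff, so the expected group-mean difference equals
    the planted diff exactly (the shift is validated at construction
    time, never clipped). Missing entries are placed independently at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    n_res, n_sen = config.n_resistant, config.n_sensitive
    res_samples = [f"R{i + 1:03d}" for i in range(n_res)]
    sen_samples = [f"S{i + 1:03d}" for i in range(n_sen)]
    samples = res_samples + sen_samples

    # site identities: genomic-style ids on one synthetic chromosome
    positions = 1000 + 100 * np.arange(n_sites)
    site_ids = [f"chr1:{p}" for p in positions]

    region_names = list(config.region_proportions)
    region_probs = np.array([config.region_proportions[r] for r in region_names])
    regions = rng.choice(region_names, size=n_sites, p=region_probs)
    gene_pool = np.array([f"g{i + 1:04d}" for i in range(config.n_genes)])
    genes = np.where(regions == "intergenic", "", rng.choice(gene_pool, size=n_sites))

    n_des = int(round(config.des_fraction * n_sites))
    is_des = np.zeros(n_sites, dtype=bool)
    des_idx = rng.choice(n_sites, size=n_des, replace=False)
    is_des[des_idx] = True
    over = rng.random(n_sites) < config.over_editing_proportion
    planted_diff = np.where(
        is_des, np.where(over, config.effect_size, -config.effect_size), 0.0
    )

    a0, b0 = _beta_params(config.beta_mean, config.beta_concentration)
    sen_vals = rng.beta(a0, b0, size=(n_sites, n_sen))
    res_vals = np.empty((n_sites, n_res))
    for i in range(n_sites):
        mean_i = config.beta_mean + planted_diff[i]
        a, b = _beta_params(mean_i, config.beta_concentration)
        res_vals[i] = rng.beta(a, b, size=n_res)
    levels = np.hstack([res_vals, sen_vals])
    if config.missing_rate > 0:
        mask = rng.random(levels.shape) < config.missing_rate
        levels = np.where(mask, np.nan, levels)

    profile = EditingProfile(
        pd.DataFrame(levels, index=pd.Index(site_ids, name="site_id"), columns=samples)
    ).validate()
    response = pd.DataFrame(
        {
            "sample": samples,
            "cancer": config.cancer,
            "drug": config.drug,
            "response_label": [RESISTANT_LABEL] * n_res + [SENSITIVE_LABEL] * n_sen,
        }
    )
    truth_sites = pd.DataFrame(
        {
            "is_des": is_des,
            "planted_diff": planted_diff,
            "region": regions,
            "gene_id": genes,
            "chrom": "chr1",
            "pos": positions,
            "strand": "+",
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    return profile, response, TruthTable(sites=truth_sites)


def truth_to_annotation(truth: TruthTable) -> pd.DataFrame:
    """Site annotation table (chrom, pos, strand, gene_id, region) from truth."""
    ann = truth.sites[["chrom", "pos", "strand", "gene_id", "region"]].copy()
    ann.index.name = "site_id"
    return ann


# ---------------------------------------------------------------------------
# ADAR expression


def simulate_adar_expression(
    oel: pd.Series, r2_target: float, seed: int
) -> pd.Series:
    """Expression linearly coupled to OEL with a chosen population R^2.

    expression = a + b*oel + noise, with the noise variance set
    analytically from the observed OEL variance so the linear-fit
    population R^2 equals ``r2_target``:
    sigma^2 = b^2 Var(oel) (1 - R^2) / R^2. With ``r2_target`` 0 the
    expression is independent of the OEL. Values are shifted to be
    nonnegative (a constant shift leaves R^2 unchanged).
    """
    if not 0 <= r2_target < 1:
        raise ValueError("r2_target must be in [0, 1); exact 1 needs zero noise")
    rng = np.random.default_rng(seed)
    x = oel.to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant OEL vector: R^2 undefined")
    var = float(np.var(x))
    intercept, slope = 10.0, 50.0  # FPKM-like scale
    if r2_target == 0:
        noise_sd = 5.0
        expr = intercept + noise_sd * rng.standard_normal(len(x))
    else:
        noise_sd = float(np.sqrt(slope**2 * var * (1 - r2_target) / r2_target))
        expr = intercept + slope * x + noise_sd * rng.standard_normal(len(x))
    if expr.min() < 0:
        expr = expr - expr.min()
    return pd.Series(expr, index=oel.index)


# ---------------------------------------------------------------------------
# UTR rewiring fixtures


def simulate_mirnas(n: int, seed: int, length: int = 22) -> dict[str, str]:
    """Random mature miRNAs whose seeds allow both gain and loss planting.

    Seed positions 2-7 are guaranteed to contain at least one C and one
    U, so the complementary UTR core contains a G (editable into
    existence) and an A (editable away).
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    out: dict[str, str] = {}
    for i in range(n):
        while True:
            seq = "".join(rng.choice(alphabet, size=length))
            core = seq[1:7]
            if "C" in core and "U" in core:
                break
        out[f"miR-{i + 1:03d}"] = seq
    return out


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def simulate_utr_rewiring(
    n_genes: int,
    mirnas: Mapping[str, str],
    n_gain: int,
    n_loss: int,
    utr_length: int = 200,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Plant seed-site gains and losses in synthetic 3'-UTRs.

    For a gain, the unedited UTR carries a seed core broken by a single
    A where the intact core has a G; editing that A restores the site,
    and the unedited UTR holds no canonical site for the miRNA anywhere.
    For a loss, an intact 8mer site is planted whose core carries an A;
    editing destroys every canonical site for the miRNA. Backgrounds are
    resampled (bounded retries) until no accidental site for the planted
    miRNA exists anywhere on the UTR, so recovery is collision-free by
    construction.

    Returns (UTR sequences keyed by gene id (RNA letters), a positions
    table with columns site_id/gene_id/utr_pos, truth triplet rows).
    """
    if utr_length < 50:
        raise ValueError("utr_length must be >= 50")
    n_events = n_gain + n_loss
    if n_events > n_genes:
        raise ValueError("more planted events than genes")
    rng = np.random.default_rng(seed)
    mirnas = {k: to_rna(v) for k, v in mirnas.items()}
    for mid, seq in mirnas.items():
        if len(seq) < 8:
            raise ValueError(f"miRNA {mid!r} shorter than 8 nt")
    gain_pool = [m for m, s in mirnas.items() if "G" in reverse_complement(s[1:7])]
    loss_pool = [m for m, s in mirnas.items() if "A" in reverse_complement(s[1:7])]
    if n_gain and not gain_pool:
        raise ValueError("no miRNA with a G in its seed-complementary core (gain)")
    if n_loss and not loss_pool:
        raise ValueError("no miRNA with an A in its seed-complementary core (loss)")

    utrs: dict[str, str] = {}
    pos_rows = []
    truth_rows = []
    genes = [f"utr_g{i + 1:03d}" for i in range(n_genes)]
    events = [("gain", gain_pool[i % len(gain_pool)]) for i in range(n_gain)]
    events += [("loss", loss_pool[i % len(loss_pool)]) for i in range(n_loss)]

    for idx, gene in enumerate(genes):
        if idx < n_events:
            kind, mirna_id = events[idx]
            target8 = seed_match_strings(mirnas[mirna_id])["8mer"]
            core = target8[1:7]
            if kind == "gain":
                j = int(rng.choice([k for k, c in enumerate(core) if c == "G"]))
                insert = target8[: 1 + j] + "A" + target8[2 + j :]
            else:
                j = int(rng.choice([k for k, c in enumerate(core) if c == "A"]))
                insert = target8
            placed = False
            for _ in range(max_retries):
                offset = int(rng.integers(1, utr_length - len(insert) - 1))
                background = _random_rna(rng, utr_length)
                utr = background[:offset] + insert + background[offset + len(insert):]
                edit_pos = offset + 1 + j + 1  # 1-based: past m8 char, into the core
                edited = utr[: edit_pos - 1] + "G" + utr[edit_pos:]
                n_before = len(find_seed_sites(mirnas[mirna_id], utr))
                n_after = len(find_seed_sites(mirnas[mirna_id], edited))
                want = (0, 1) if kind == "gain" else (1, 0)
                if (n_before, n_after) == want and utr[edit_pos - 1] == "A":
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a collision-free {kind} for {mirna_id} "
                    f"after {max_retries} retries"
                )
            site_id = f"utr_site_{gene}"
            utrs[gene] = utr
            pos_rows.append((site_id, gene, edit_pos))
            truth_rows.append((site_id, mirna_id, gene, kind))
        else:
            # decoy UTR: no canonical site for any planted miRNA
            planted = {m for _, m in events}
            for _ in range(max_retries):
                utr = _random_rna(rng, utr_length)
                if all(not find_seed_sites(mirnas[m], utr) for m in planted):
                    break
            else:
                raise RuntimeError("could not generate a site-free decoy UTR")
            utrs[gene] = utr
    positions = pd.DataFrame(pos_rows, columns=["site_id", "gene_id", "utr_pos"])
    truth = pd.DataFrame(truth_rows, columns=["site_id", "mirna_id", "gene_id", "kind"])
    return utrs, positions, truth


# ---------------------------------------------------------------------------
# expression for triplets


def simulate_expression_for_triplets(
    triplets: pd.DataFrame,
    labels: pd.Series,
    correlation_strength: float = 0.9,
    seed: int = 0,
    decoy_genes: list[str] | None = None,
    decoy_mirnas: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene and miRNA expression implementing the planted triplet logic.

    ``labels`` maps sample -> {"resistant", "sensitive"}. Planted events
    are interpreted as over-edited DESs, so a gain's interaction is
    active in resistant samples: there the miRNA-gene Pearson
    correlation is negative with magnitude ``correlation_strength`` and
    the gene mean is lower, while the other group is uncorrelated. For a
    loss the roles swap. miRNA group means are equal (non-DE). Decoy
    genes and miRNAs are independent noise in both groups.
    """
    if not 0 < correlation_strength <= 1:
        raise ValueError("correlation_strength must be in (0, 1]")
    res = [s for s, g in labels.items() if g == "resistant"]
    sen = [s for s, g in labels.items() if g == "sensitive"]
    if len(res) < 3 or len(sen) < 3:
        raise ValueError("need >= 3 samples per group")
    rng = np.random.default_rng(seed)
    samples = res + sen
    mirna_mu, mirna_sd = 50.0, 10.0
    gene_sd = 15.0
    hi_mean, lo_mean = 100.0, 70.0

    gene_rows: dict[str, np.ndarray] = {}
    mirna_rows: dict[str, np.ndarray] = {}

    def correlated(m_vals: np.ndarray, mu: float, rho: float) -> np.ndarray:
        z = rng.standard_normal(len(m_vals))
        g = mu - rho * (gene_sd / mirna_sd) * (m_vals - m_vals.mean())
        g = g + np.sqrt(max(0.0, 1 - rho**2)) * gene_sd * z
        return np.maximum(g, 0.01)

    def draw_mirna() -> np.ndarray:
        # planted miRNAs are non-DE by construction: with equal group sizes
        # the sensitive group reuses a permutation of the resistant values,
        # so the rank-sum test sees identical group distributions exactly
        vals_res = np.maximum(
            mirna_mu + mirna_sd * rng.standard_normal(len(res)), 0.01
        )
        if len(sen) == len(res):
            vals_sen = rng.permutation(vals_res)
        else:
            vals_sen = np.maximum(
                mirna_mu + mirna_sd * rng.standard_normal(len(sen)), 0.01
            )
        return np.concatenate([vals_res, vals_sen])

    for _, row in triplets.iterrows():
        mirna_id, gene_id, kind = row["mirna_id"], row["gene_id"], row["kind"]
        if mirna_id not in mirna_rows:
            mirna_rows[mirna_id] = draw_mirna()
        m = mirna_rows[mirna_id]
        m_res, m_sen = m[: len(res)], m[len(res):]
        if kind == "gain":  # interaction active in resistant, gene repressed there
            g_res = correlated(m_res, lo_mean, correlation_strength)
            g_sen = np.maximum(hi_mean + gene_sd * rng.standard_normal(len(sen)), 0.01)
        else:  # loss: interaction active in sensitive, gene repressed there
            g_res = np.maximum(hi_mean + gene_sd * rng.standard_normal(len(res)), 0.01)
            g_sen = correlated(m_sen, lo_mean, correlation_strength)
        gene_rows[gene_id] = np.concatenate([g_res, g_sen])

    for gid in decoy_genes or []:
        if gid not in gene_rows:
            gene_rows[gid] = np.maximum(
                hi_mean + gene_sd * rng.standard_normal(len(samples)), 0.01
            )
    for mid in decoy_mirnas or []:
        if mid not in mirna_rows:
            mirna_rows[mid] = np.maximum(
                mirna_mu + mirna_sd * rng.standard_normal(len(samples)), 0.01
            )

    gene_expr = pd.DataFrame(gene_rows, index=samples).T.sort_index()
    mirna_expr = pd.DataFrame(mirna_rows, index=samples).T.sort_index()
    gene_expr.index.name = "feature_id"
    mirna_expr.index.name = "feature_id"
    return gene_expr, mirna_expr


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    groups: pd.Series,
    hr: float,
    censoring_rate: float,
    seed: int,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival with a planted hazard ratio between groups.

    ``groups`` maps sample -> {"over", "under"} (or any two labels where
    "over" marks the exposed group). Event times are exponential with
    hazard ``baseline_hazard`` (under) and ``baseline_hazard * hr``
    (over). Censoring is independent: each sample is censored with
    probability ``censoring_rate`` at a uniform fraction of its event
    time. Columns: sample, time (> 0), event (0/1).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censoring_rate <= 1:
        raise ValueError("censoring_rate must be in [0, 1]")
    over = groups == "over"
    if over.all() or (~over).all():
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    hazard = np.where(over.to_numpy(), baseline_hazard * hr, baseline_hazard)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(len(times)) < censoring_rate
    obs = np.where(censored, times * rng.uniform(0.0, 1.0, len(times)), times)
    obs = np.maximum(obs, 1e-9)  # strictly positive times
    return pd.DataFrame(
        {"sample": groups.index, "time": obs, "event": (~censored).astype(int)}
    )
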