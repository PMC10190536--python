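"""Editing-aware miRNA target rewiring on 3'-UTRs.

A-to-I editing is read as A->G by the ribosome and by base-pairing, so
an edit inside a 3'-UTR can create or destroy a canonical miRNA seed
site. This module detects canonical seed sites (8mer, 7mer-m8, 7mer-A1,
no wobble pairing), applies in-silico A->G edits, classifies gain/loss
rewiring events around edited positions, and screens rewiring events
against expression data to produce (DES, miRNA, gene) triplets.

Sequences are handled internally as RNA (ACGU, uppercase); DNA input
(ACGT) is normalized transparently. UTR coordinates are 1-based on the
transcript strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .editing_core import log2_fold_change, rank_de
from .io_formats import Condition

log = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}
_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def to_rna(seq: str) -> str:
    """Normalize to uppercase RNA letters; reject anything outside ACGU/ACGT."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains letters outside ACGU/ACGT: {sorted(bad)}")
    return out


def to_dna(seq: str) -> str:
    """RNA -> DNA letters for FASTA output (lossless U<->T mapping)."""
    return seq.upper().replace("U", "T")


def reverse_complement(rna: str) -> str:
    return "".join(_RC[c] for c in reversed(rna))


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    gene_id: str
    utr_start: int  # 1-based start of the matched site on the UTR
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1

    @property
    def utr_end(self) -> int:
        """1-based inclusive end of the matched site."""
        return self.utr_start + _SITE_LENGTH[self.site_type] - 1


@dataclass
class RewiringEvent:
    site_id: str
    gene_id: str
    mirna_id: str
    utr_pos: int  # edited position, 1-based on the UTR
    kind: str  # gain | loss
    unedited_sites: list[SeedSite] = field(default_factory=list)
    edited_sites: list[SeedSite] = field(default_factory=list)


@dataclass
class Triplet:
    event: RewiringEvent
    direction: str  # DES direction: over | under
    r_res: float
    p_res: float
    r_sen: float
    p_sen: float
    gene_log2fc: float
    mirna_de_p: float
    corr_ok: bool
    fc_ok: bool
    mirna_ok: bool
    extended_rule: bool = False  # True when the under-edited symmetric rule fired

    @property
    def passed(self) -> bool:
        return self.corr_ok and self.fc_ok and self.mirna_ok


# ---------------------------------------------------------------------------
# seed-site detection


def seed_match_strings(mirna: str) -> dict[str, str]:
    """The UTR substrings that constitute each canonical site type.

    The miRNA seed is positions 2-8 (1-based, 5'->3'). On the UTR:
    8mer    = reverse complement of positions 2-8, followed by A;
    7mer-m8 = reverse complement of positions 2-8;
    7mer-A1 = reverse complement of positions 2-7, followed by A.
    """
    mirna = to_rna(mirna)
    if len(mirna) < 8:
        raise ValueError(f"miRNA must be >= 8 nt, got {len(mirna)}")
    m2_8 = reverse_complement(mirna[1:8])  # 7 nt on the UTR
    m2_7 = reverse_complement(mirna[1:7])  # 6 nt on the UTR
    return {"8mer": m2_8 + "A", "7mer-m8": m2_8, "7mer-A1": m2_7 + "A"}


def find_seed_sites(
    mirna_seq: str, utr_seq: str, mirna_id: str = "", gene_id: str = ""
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one UTR.

    Every window is scanned with exact Watson-Crick matching (no G:U
    wobble). Overlapping matches at the same locus report only the
    strongest type (8mer > 7mer-m8 > 7mer-A1): loci are anchored at the
    6-nt core complementary to miRNA positions 2-7.
    """
    utr = to_rna(utr_seq)
    patterns = seed_match_strings(mirna_seq)
    core = patterns["7mer-m8"][1:]  # complement of positions 2-7, 6 nt
    m8_char = patterns["7mer-m8"][0]
    sites: list[SeedSite] = []
    for i in range(len(utr) - len(core) + 1):  # 0-based core start
        if utr[i : i + len(core)] != core:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8_char
        has_a1 = i + len(core) < len(utr) and utr[i + len(core)] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(mirna_id, gene_id, i, "8mer"))  # starts at m8
        elif has_m8:
            sites.append(SeedSite(mirna_id, gene_id, i, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(mirna_id, gene_id, i + 1, "7mer-A1"))
        # bare 6mer core: below the canonical site types, not reported
    return sites


# ---------------------------------------------------------------------------
# in-silico editing


def edit_sequence(utr_seq: str, edit_positions: Iterable[int]) -> str:
    """Apply A->G edits at 1-based positions on the transcript strand.

    Every position must hold an A; anything else is an error, which
    guards against strand or coordinate bookkeeping bugs upstream.
    """
    utr = to_rna(utr_seq)
    chars = list(utr)
    for pos in edit_positions:
        if not 1 <= pos <= len(chars):
            raise ValueError(f"edit position {pos} outside UTR of length {len(chars)}")
        if chars[pos - 1] != "A":
            raise ValueError(
                f"position {pos} holds {chars[pos - 1]!r}, expected A "
                "(check strand and coordinate conventions)"
            )
        chars[pos - 1] = "G"
    return "".join(chars)


def _sites_overlapping(sites: Iterable[SeedSite], pos: int) -> list[SeedSite]:
    return [s for s in sites if s.utr_start <= pos <= s.utr_end]


def _core_anchor(site: SeedSite) -> int:
    """1-based start of the 6-nt core locus shared by all three site types."""
    return site.utr_start + 1 if site.site_type in ("8mer", "7mer-m8") else site.utr_start


def classify_rewiring(
    utr_seq: str,
    des_positions: Mapping[str, int],
    mirnas: Mapping[str, str],
    gene_id: str = "",
) -> list[RewiringEvent]:
    """Gain/loss classification of seed sites around edited positions.

    Each DES position is edited independently and, per miRNA, the seed
    sites whose footprint overlaps the edited position are compared
    between the unedited and the edited sequence, matched by their 6-nt
    core locus. A gain is a core locus that hosts a canonical site only
    after editing; a loss is one that hosts a site only before. A type
    change at a surviving locus (e.g. an 8mer weakening to a 7mer-m8
    when the A1 adenosine is edited) is not called, because a canonical
    site still exists there. Distal sites elsewhere on the UTR never
    produce events.
    """
    utr = to_rna(utr_seq)
    events: list[RewiringEvent] = []
    for site_id, pos in des_positions.items():
        edited = edit_sequence(utr, [pos])
        for mirna_id, mirna_seq in mirnas.items():
            before_all = find_seed_sites(mirna_seq, utr, mirna_id, gene_id)
            after_all = find_seed_sites(mirna_seq, edited, mirna_id, gene_id)
            before_hit = _sites_overlapping(before_all, pos)
            after_hit = _sites_overlapping(after_all, pos)
            anchors_before = {_core_anchor(s) for s in before_all}
            anchors_after = {_core_anchor(s) for s in after_all}
            gained = [s for s in after_hit if _core_anchor(s) not in anchors_before]
            lost = [s for s in before_hit if _core_anchor(s) not in anchors_after]
            if gained:
                events.append(
                    RewiringEvent(site_id, gene_id, mirna_id, pos, "gain",
                                  before_hit, after_hit)
                )
            if lost:
                events.append(
                    RewiringEvent(site_id, gene_id, mirna_id, pos, "loss",
                                  before_hit, after_hit)
                )
    return events


# ---------------------------------------------------------------------------
# triplet screen


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluate_triplet(
    event: RewiringEvent,
    direction: str,
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    condition: Condition,
    mirna_de: pd.DataFrame,
    alpha: float = 0.05,
    fc_pseudocount: float = 0.0,
) -> Triplet:
    """Apply the three expression-level criteria to one rewiring event.

    With an over-edited DES the edited (rewired) form dominates in
    resistant samples; with an under-edited DES it dominates in sensitive
    samples, so the group roles swap (the symmetric extended rule). The
    group in which the miRNA-gene interaction is active must show a
    significantly negative Pearson correlation (r < 0, p < alpha) that
    the other group lacks, the gene's fold change must point away from
    the repressed group, and the miRNA itself must not be differentially
    expressed (rank-sum p >= alpha).
    """
    if direction not in ("over", "under"):
        raise ValueError(f"unknown DES direction: {direction!r}")
    res_cols = [s for s in gene_expr.columns if s in condition.resistant]
    sen_cols = [s for s in gene_expr.columns if s in condition.sensitive]
    g_res = gene_expr.loc[event.gene_id, res_cols].to_numpy(dtype=float)
    g_sen = gene_expr.loc[event.gene_id, sen_cols].to_numpy(dtype=float)
    m_res = mirna_expr.loc[event.mirna_id, res_cols].to_numpy(dtype=float)
    m_sen = mirna_expr.loc[event.mirna_id, sen_cols].to_numpy(dtype=float)
    r_res, p_res = _pearson(m_res, g_res)
    r_sen, p_sen = _pearson(m_sen, g_sen)
    lfc = log2_fold_change(gene_expr.loc[event.gene_id], condition, fc_pseudocount)

    # group in which the miRNA-gene interaction is active
    interaction_in_resistant = (direction == "over") == (event.kind == "gain")
    sig_neg_res = (r_res < 0) and (p_res < alpha)
    sig_neg_sen = (r_sen < 0) and (p_sen < alpha)
    if interaction_in_resistant:
        corr_ok = sig_neg_res and not sig_neg_sen
        fc_ok = lfc < 0  # gene repressed in resistant samples
    else:
        corr_ok = sig_neg_sen and not sig_neg_res
        fc_ok = lfc > 0
    mirna_p = float(mirna_de.loc[event.mirna_id, "p"])
    return Triplet(
        event=event, direction=direction,
        r_res=r_res, p_res=p_res, r_sen=r_sen, p_sen=p_sen,
        gene_log2fc=lfc, mirna_de_p=mirna_p,
        corr_ok=corr_ok, fc_ok=fc_ok, mirna_ok=mirna_p >= alpha,
        extended_rule=direction == "under",
    )


def screen_triplets(
    events: Sequence[RewiringEvent],
    des_records: pd.DataFrame,
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    condition: Condition,
    alpha: float = 0.05,
    under_edited_rule: bool = True,
    fc_pseudocount: float = 0.0,
) -> list[Triplet]:
    """Multi-step triplet screen over rewiring events.

    Each event's DES must carry a direction in ``des_records``. Events
    with fewer than 3 expression pairs in a group, or missing expression
    rows, are skipped with a warning. Only triplets passing all three
    criteria are returned; under-edited DESs are handled by the symmetric
    extended rule unless ``under_edited_rule`` is off.
    """
    res_n = len([s for s in gene_expr.columns if s in condition.resistant])
    sen_n = len([s for s in gene_expr.columns if s in condition.sensitive])
    if res_n < 3 or sen_n < 3:
        raise ValueError("need >= 3 expression samples per group")
    mirna_ids = sorted({e.mirna_id for e in events} & set(mirna_expr.index))
    mirna_de = (
        rank_de(mirna_expr.loc[mirna_ids], condition)
        if mirna_ids
        else pd.DataFrame(columns=["p", "log2fc"])
    )
    out: list[Triplet] = []
    for event in events:
        if event.site_id not in des_records.index:
            log.warning("screen_triplets: %s not in DES table, skipped", event.site_id)
            continue
        direction = str(des_records.loc[event.site_id, "direction"])
        if direction == "under" and not under_edited_rule:
            log.info("screen_triplets: %s under-edited, extended rule off", event.site_id)
            continue
        if event.gene_id not in gene_expr.index or event.mirna_id not in mirna_expr.index:
            log.warning(
                "screen_triplets: missing expression for %s/%s, skipped",
                event.gene_id, event.mirna_id,
            )
            continue
        trip = evaluate_triplet(
            event, direction, gene_expr, mirna_expr, condition, mirna_de,
            alpha=alpha, fc_pseudocount=fc_pseudocount,
        )
        if trip.passed:
            out.append(trip)
    return out


def triplets_to_frame(triplets: Sequence[Triplet]) -> pd.DataFrame:
    rows = [
        (
            t.event.site_id, t.event.mirna_id, t.event.gene_id, t.event.kind,
            t.direction, t.r_res, t.p_res, t.r_sen, t.p_sen, t.gene_log2fc,
            t.mirna_de_p, t.extended_rule,
        )
        for t in triplets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "mirna_id", "gene_id", "kind", "direction",
            "r_res", "p_res", "r_sen", "p_sen", "gene_log2fc",
            "mirna_de_p", "extended_rule",
        ],
    )


# ---------------------------------------------------------------------------
# motif-window export


def extract_windows(
    positions: Mapping[str, tuple[str, int]],
    contigs: Mapping[str, str],
    flank: int = 20,
) -> dict[str, str]:
    """Extract +/- ``flank`` nt windows centered on each site.

    ``positions`` maps site_id -> (contig_id, 1-based position). Windows
    are truncated at contig ends (with a warning); a position outside its
    contig is an error. Records are keyed by site id and suitable as
    input FASTA for external motif-discovery tools.
    """
    out: dict[str, str] = {}
    for site_id, (contig_id, pos) in positions.items():
        seq = contigs[contig_id]
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"site {site_id!r}: position {pos} outside contig {contig_id!r} "
                f"of length {len(seq)}"
            )
        start = max(1, pos - flank)
        end = min(len(seq), pos + flank)
        if start > pos - flank or end < pos + flank:
            log.warning("extract_windows: window for %s truncated at contig end", site_id)
        out[site_id] = seq[start - 1 : end]
    return out
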