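"""Transcription-factor target-set analysis: PWM scanning, target-set
activity tests, site interaction, gene-set enrichment, over-representation.

PWM similarity is probability-sum scoring, min-max scaled per matrix:
``similarity = (score - min_score) / (max_score - min_score)`` with
``score = sum_i matrix[base_i, i]``, so the consensus scores exactly 1
and the worst window exactly 0.  Both strands are scanned.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EXHAUSTIVE_LIMIT = 10_000


class RegulatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------


@dataclass
class Pwm:
    """Position frequency/probability matrix, 4 x L in A,C,G,T row order.

    The raw matrix is pseudocount-regularized and column-normalized at
    construction so that no base has zero probability.
    """

    tf_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 4:
            raise RegulatorError(f"PWM {self.tf_id}: need 4 x L matrix with L >= 4")
        if (mat < 0).any():
            raise RegulatorError(f"PWM {self.tf_id}: negative entries")
        mat = mat + self.pseudocount
        self.matrix = mat / mat.sum(axis=0, keepdims=True)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def _similarities(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Min-max-scaled probability-sum score of every window; windows
    containing non-ACGT characters score -inf."""
    L = pwm.length
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    lo = pwm.matrix.min(axis=0).sum()
    hi = pwm.matrix.max(axis=0).sum()
    padded = np.vstack([pwm.matrix, np.full((1, L), -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = padded[windows, np.arange(L)].sum(axis=1)
    return (scores - lo) / (hi - lo)


def scan_pwm(
    sequence: str, pwm: Pwm, min_similarity: float = 0.95
) -> List[Tuple[int, str, float]]:
    """All windows on either strand with similarity >= threshold.

    Offsets are 0-based positions of the window start on the forward
    strand; results are sorted by offset then strand.
    """
    if not 0 < min_similarity <= 1:
        raise RegulatorError("min_similarity must be in (0, 1]")
    seq = sequence.upper()
    if len(seq) < pwm.length:
        raise RegulatorError("sequence shorter than motif")
    hits: List[Tuple[int, str, float]] = []
    fwd = _similarities(_encode(seq), pwm)
    for off in np.flatnonzero(fwd >= min_similarity):
        hits.append((int(off), "+", float(fwd[off])))
    rev = _similarities(_encode(reverse_complement(seq)), pwm)
    L = pwm.length
    for off in np.flatnonzero(rev >= min_similarity):
        hits.append((len(seq) - L - int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# Target sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSet:
    tf_id: str
    region_scope: str  # promoter_1kb | promoter_10kb | intron
    gene_ids: FrozenSet[str]


def build_target_sets(
    sequences: Mapping[str, str],
    pwm_library: Mapping[str, Pwm],
    scope: str,
    min_similarity: float = 0.95,
) -> Dict[str, TargetSet]:
    """Gene is a TF's target iff the scoped sequence has >= 1 PWM match.

    ``sequences`` maps gene -> sequence of the requested scope; genes
    without a scoped sequence are simply absent (the caller warns).
    """
    sets: Dict[str, TargetSet] = {}
    for tf_id in sorted(pwm_library):
        pwm = pwm_library[tf_id]
        members: Set[str] = set()
        for gene in sorted(sequences):
            seq = sequences[gene]
            if len(seq) < pwm.length:
                warnings.warn(f"gene {gene}: {scope} sequence shorter than {tf_id} motif; excluded")
                continue
            if scan_pwm(seq, pwm, min_similarity):
                members.add(gene)
        sets[tf_id] = TargetSet(tf_id, scope, frozenset(members))
    return sets


def target_set_activity(
    changes: Mapping[str, float], targets: Iterable[str]
) -> Tuple[float, float, float]:
    """Welch test of target vs non-target percent change.

    Returns (mean_targets, mean_nontargets, p).  Genes without a change
    value are ignored, so the test is invariant to adding unmeasured
    genes.
    """
    chg = pd.Series(dict(changes)).dropna()
    target_set = set(targets)
    t_vals = chg[chg.index.isin(target_set)].to_numpy()
    n_vals = chg[~chg.index.isin(target_set)].to_numpy()
    if len(t_vals) < 2 or len(n_vals) < 2:
        raise RegulatorError("need >= 2 targets and >= 2 non-targets with change values")
    if np.ptp(np.concatenate([t_vals, n_vals])) == 0:
        return float(t_vals.mean()), float(n_vals.mean()), 1.0
    res = stats.ttest_ind(t_vals, n_vals, equal_var=False)
    return float(t_vals.mean()), float(n_vals.mean()), float(res.pvalue)


def interaction_test(
    set_a: TargetSet, set_b: TargetSet, changes: Mapping[str, float]
) -> Dict[str, float]:
    """Compare genes carrying both motifs against single-motif genes.

    Partitions the measured genes into both / A-only / B-only / neither
    and Welch-tests both-vs-A-only and both-vs-B-only.
    """
    chg = pd.Series(dict(changes)).dropna()
    both = chg.index.isin(set_a.gene_ids & set_b.gene_ids)
    a_only = chg.index.isin(set_a.gene_ids - set_b.gene_ids)
    b_only = chg.index.isin(set_b.gene_ids - set_a.gene_ids)
    if not both.any():
        raise RegulatorError("no gene carries both motifs")
    out = {
        "mean_both": float(chg[both].mean()),
        "mean_a_only": float(chg[a_only].mean()) if a_only.any() else np.nan,
        "mean_b_only": float(chg[b_only].mean()) if b_only.any() else np.nan,
        "n_both": int(both.sum()),
        "n_a_only": int(a_only.sum()),
        "n_b_only": int(b_only.sum()),
    }
    for key, sel in (("p_both_vs_a", a_only), ("p_both_vs_b", b_only)):
        if both.sum() >= 2 and sel.sum() >= 2:
            out[key] = float(stats.ttest_ind(chg[both], chg[sel], equal_var=False).pvalue)
        else:
            out[key] = np.nan
    return out


# ---------------------------------------------------------------------------
# Gene-set enrichment (weighted running-sum)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    es: float
    p: float
    direction: str  # "up" | "down"
    n_hits: int
    running_sum: Tuple[float, ...] = field(repr=False, default=())


def _running_es(stat_sorted: np.ndarray, is_hit: np.ndarray, weight: float) -> Tuple[float, np.ndarray]:
    """Enrichment score of a ranked list: hits step up proportionally to
    |stat|^weight, misses step down by 1/(N - N_hits); ES is the
    extremum of the running sum, which ends at 0 by construction."""
    n = len(stat_sorted)
    n_hits = int(is_hit.sum())
    inc = np.abs(stat_sorted) ** weight
    hit_norm = inc[is_hit].sum()
    steps = np.where(
        is_hit,
        inc / hit_norm if hit_norm > 0 else 1.0 / max(n_hits, 1),
        -1.0 / (n - n_hits),
    )
    running = np.cumsum(steps)
    extremum = running[np.argmax(np.abs(running))]
    return float(extremum), running


def gsea_enrichment(
    ranked_stats: Mapping[str, float],
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_id: str = "",
    min_set_size: int = 3,
) -> EnrichmentResult:
    """Concordance of a gene set within a signed ranked list.

    The list is ranked by decreasing statistic; significance is by
    gene-label permutation (random same-size sets), exhaustive when the
    number of distinct sets is at most ``EXHAUSTIVE_LIMIT``.  Sets
    smaller than ``min_set_size`` after intersection with the list are
    rejected (relax the floor explicitly for degenerate checks).
    """
    stat = pd.Series(dict(ranked_stats)).astype(float)
    members = set(gene_set) & set(stat.index)
    if len(members) < max(min_set_size, 1):
        raise RegulatorError(
            f"gene set smaller than {min_set_size} after intersection with the ranked list"
        )
    order = stat.sort_values(ascending=False, kind="stable")
    values = order.to_numpy()
    is_hit = order.index.isin(members).astype(bool)
    es, running = _running_es(values, is_hit, weight)

    n, k = len(values), len(members)
    total = math.comb(n, k)
    rng = np.random.default_rng(seed)
    if total <= EXHAUSTIVE_LIMIT:
        perm_es = np.empty(total)
        for i, combo in enumerate(itertools.combinations(range(n), k)):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perm_es[i] = _running_es(values, mask, weight)[0]
        p = float((np.abs(perm_es) >= abs(es)).mean())
    else:
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            perm_es[i] = _running_es(values, mask, weight)[0]
        p = float((1 + (np.abs(perm_es) >= abs(es)).sum()) / (1 + n_perm))
    return EnrichmentResult(
        set_id=set_id,
        es=es,
        p=p,
        direction="up" if es >= 0 else "down",
        n_hits=k,
        running_sum=tuple(running),
    )


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------


def overrepresentation_test(
    subset: Iterable[str], category: Iterable[str], background: Iterable[str]
) -> Tuple[int, float]:
    """Hypergeometric upper-tail p of the subset/category overlap within
    the background universe."""
    bg = set(background)
    sub = set(subset)
    cat = set(category) & bg
    if not sub <= bg:
        raise RegulatorError("subset not contained in background")
    overlap = len(sub & cat)
    p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(cat), len(sub)))
    return overlap, min(p, 1.0)
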