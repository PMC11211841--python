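"""Evaluation metrics: sequence recovery, internal diversity, base-pair F1,
dot-bracket parsing, and the length categories used for benchmark stratification.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align


class MetricError(ValueError):
    pass


def recovery_rate(generated: str, native: str) -> float:
    """Fraction of positions where the generated sequence matches the native."""
    if len(generated) != len(native):
        raise MetricError(f"length mismatch: {len(generated)} vs {len(native)}")
    if not native:
        raise MetricError("empty sequences")
    return sum(a == b for a, b in zip(generated, native)) / len(native)


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_sim(s1: str, s2: str, mode: str = "global") -> float:
    """Aligned-subsequence ratio: identity-scored alignment length over the
    shorter sequence's length.

    With zero gap penalties the global alignment score equals the longest
    common subsequence length, the most literal reading of "aligned
    subsequence"; ``mode='local'`` switches to local alignment.
    """
    if not s1 or not s2:
        raise MetricError("pairwise_sim requires non-empty sequences")
    score = _aligner(mode).score(s1, s2)
    return float(score) / min(len(s1), len(s2))


def int_div(G: list[str], mode: str = "global") -> float:
    """Internal diversity: 1 - mean similarity over all ordered pairs,
    self-pairs included (the |G|^2 normalizer)."""
    if not G:
        raise MetricError("int_div requires at least one sequence")
    n = len(G)
    total = 0.0
    for a in range(n):
        total += 1.0  # self-pair similarity
        for b in range(a + 1, n):
            total += 2.0 * pairwise_sim(G[a], G[b], mode=mode)
    return 1.0 - total / (n * n)


def basepair_f1(pred_pairs: set[tuple[int, int]], ref_pairs: set[tuple[int, int]],
                both_empty_value: float = 1.0) -> tuple[float, float, float]:
    """Precision/recall/F1 on exact base-pair matches (0-based, i < j).

    Two empty sets agree perfectly and score ``both_empty_value`` (default 1.0).
    """
    for pair in list(pred_pairs) + list(ref_pairs):
        i, j = pair
        if i >= j:
            raise MetricError(f"base pair must have i < j, got {pair}")
    if not pred_pairs and not ref_pairs:
        return both_empty_value, both_empty_value, both_empty_value
    tp = len(pred_pairs & ref_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 0.0
    recall = tp / len(ref_pairs) if ref_pairs else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1


_BRACKETS = {")": "(", "]": "[", "}": "{", ">": "<"}


def parse_dotbracket(s: str) -> set[tuple[int, int]]:
    """Base pairs from dot-bracket notation; ()[]{}<> each get their own stack
    (pseudoknots supported), '.' is unpaired."""
    stacks: dict[str, list[int]] = {c: [] for c in _BRACKETS.values()}
    pairs = set()
    for idx, c in enumerate(s):
        if c == ".":
            continue
        if c in stacks:
            stacks[c].append(idx)
        elif c in _BRACKETS:
            stack = stacks[_BRACKETS[c]]
            if not stack:
                raise MetricError(f"unbalanced {c!r} at position {idx}")
            pairs.add((stack.pop(), idx))
        else:
            raise MetricError(f"invalid dot-bracket character {c!r} at position {idx}")
    for opener, stack in stacks.items():
        if stack:
            raise MetricError(f"unclosed {opener!r} at position {stack[-1]}")
    return pairs


def length_category(n: int) -> str:
    """Benchmark length bins: short (<= 50 nt), medium (51-100 nt), long (> 100 nt)."""
    if n < 1:
        raise MetricError("length must be >= 1")
    if n <= 50:
        return "short"
    if n <= 100:
        return "medium"
    return "long"
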