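"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written the slow, obvious way — explicit loops, python
sets, direct formula transcription — and deliberately shares no code with
the package.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_finger_candidates(seq: str) -> list[int]:
    """Every offset where a 28-aa window has C at 3,6 and H at 19,23 (1-based)."""
    out = []
    for i in range(len(seq) - 27):
        w = seq[i : i + 28]
        if w[2] == "C" and w[5] == "C" and w[18] == "H" and w[22] == "H":
            out.append(i)
    return out


def brute_greedy_fingers(seq: str) -> list[int]:
    """Greedy left-to-right non-overlapping selection of candidate offsets."""
    chosen = []
    last_end = 0
    for i in brute_finger_candidates(seq):
        if i >= last_end:
            chosen.append(i)
            last_end = i + 28
    return chosen


def brute_runs(offsets: list[int], gap_tol: int, min_fingers: int) -> list[list[int]]:
    """Direct run-length grouping of finger offsets."""
    runs: list[list[int]] = []
    for off in offsets:
        if runs and 0 <= off - runs[-1][-1] - 28 <= gap_tol:
            runs[-1].append(off)
        else:
            runs.append([off])
    return [r for r in runs if len(r) >= min_fingers]


def brute_heterozygosity(seqs: list[str]) -> list[float]:
    """x_k = 1 - sum_i f_i^2, transcribed directly."""
    n = len(seqs)
    out = []
    for k in range(len(seqs[0])):
        counts = Counter(s[k] for s in seqs)
        out.append(1.0 - sum((c / n) ** 2 for c in counts.values()))
    return out


def brute_P(x: list[float], binding: set[int]) -> float | None:
    num = sum(v for k, v in enumerate(x, start=1) if k in binding)
    den = sum(x)
    return None if den == 0 else num / den


def average_ranks(values: list[float]) -> list[float]:
    """Average (midrank) ranks of a list, computed by sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(a: list[float], b: list[float]) -> float:
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def brute_partial_spearman(
    y: list[float], x: list[float], controls: list[list[float]]
) -> float:
    """Rank everything, residualize controls out by normal equations, Pearson."""
    import numpy as np

    ry = average_ranks(y)
    rx = average_ranks(x)
    design = np.column_stack(
        [np.ones(len(y))] + [average_ranks(c) for c in controls]
    )
    beta_y = np.linalg.solve(design.T @ design, design.T @ np.array(ry))
    beta_x = np.linalg.solve(design.T @ design, design.T @ np.array(rx))
    res_y = list(np.array(ry) - design @ beta_y)
    res_x = list(np.array(rx) - design @ beta_x)
    return pearson(res_y, res_x)


def brute_score(seq: str, matrix, background=None, pseudocount=0.01) -> float:
    """Log2-odds score via explicit loops over columns."""
    bg = background or [0.25] * 4
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for j, base in enumerate(seq.upper()):
        if base == "N":
            continue
        p = (matrix[j][idx[base]] + pseudocount) / (1 + 4 * pseudocount)
        total += math.log2(p / bg[idx[base]])
    return total


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def brute_scan(seq: str, matrix, threshold: float, pseudocount=0.01):
    """All (start, strand, score) with score >= threshold, both strands."""
    L = len(matrix)
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        s = brute_score(window, matrix, pseudocount=pseudocount)
        if s >= threshold:
            hits.append((i, "+", s))
        s = brute_score(revcomp(window), matrix, pseudocount=pseudocount)
        if s >= threshold:
            hits.append((i, "-", s))
    return hits


def brute_nearest_interval(w_start, w_end, features) -> float:
    """Min gap between [w_start, w_end) and any feature; 0 on overlap."""
    best = math.inf
    for f_start, f_end in features:
        if f_start < w_end and f_end > w_start:
            return 0.0
        if f_start >= w_end:
            best = min(best, f_start - w_end)
        else:
            best = min(best, w_start - f_end)
    return best


def brute_nearest_point(p, features) -> float:
    best = math.inf
    for f_start, f_end in features:
        if f_start <= p < f_end:
            return 0.0
        best = min(best, f_start - p if p < f_start else p - f_end)
    return best


def brute_overlap_bp(w_start, w_end, peaks) -> int:
    """bp of [w_start, w_end) covered by the peak union, one bp at a time."""
    covered = set()
    for p_start, p_end in peaks:
        covered.update(range(max(w_start, p_start), min(w_end, p_end)))
    return len(covered)


def brute_chisq(table) -> float:
    """Pearson chi-squared, sum (O - E)^2 / E on a 2x2 table."""
    row = [sum(r) for r in table]
    col = [sum(c) for c in zip(*table)]
    total = sum(row)
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2
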