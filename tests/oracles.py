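"""Independent brute-force oracles used to cross-check the package.

Everything here is written with plain loops and direct formulas, on
purpose: these implementations must stay independent of the code paths
they verify.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple


def top_entries(values: Sequence[str], k: int = 3) -> List[Tuple[str, int]]:
    counts: Dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def distinct_count(values: Sequence[str]) -> int:
    seen = set()
    for v in values:
        seen.add(v)
    return len(seen)


def bool_counts(values: Sequence[bool]) -> Tuple[int, int]:
    t = f = 0
    for v in values:
        if v:
            t += 1
        else:
            f += 1
    return t, f


def ratio_summary(values: Sequence[float]) -> dict:
    n = len(values)
    total = 0.0
    for v in values:
        total += v
    mean = total / n
    ordered = sorted(values)
    mid = n // 2
    median = ordered[mid] if n % 2 == 1 else (ordered[mid - 1] + ordered[mid]) / 2.0
    if n > 1:
        ssq = 0.0
        for v in values:
            ssq += (v - mean) ** 2
        sd = math.sqrt(ssq / (n - 1))
    else:
        sd = 0.0
    return {"min": min(values), "max": max(values), "mean": mean,
            "median": median, "stddev": sd, "n": n}


def histogram_counts(values: Sequence[float], n_bins: int) -> List[int]:
    """O(n * bins) binning: equal-width bins over [lo, hi], last bin closed."""
    lo, hi = min(values), max(values)
    if lo == hi:
        return [len(values)]
    step = (hi - lo) / n_bins
    edges = [lo + i * step for i in range(n_bins)] + [hi]
    counts = [0] * n_bins
    for v in values:
        for i in range(n_bins):
            last = i == n_bins - 1
            if edges[i] <= v < edges[i + 1] or (last and v == hi):
                counts[i] += 1
                break
    return counts


def path_instances(clinical) -> Dict[tuple, List[str]]:
    """Subject keys per positional path, one entry per instance."""
    out: Dict[tuple, List[str]] = {}

    def visit(subject_key, inst):
        out.setdefault(tuple(inst.path), []).append(subject_key)
        for child in inst.children:
            visit(subject_key, child)

    for subject in clinical.subjects:
        for inst in subject.instances:
            visit(subject.subject_key, inst)
    return out


def item_raw_values(clinical, path: tuple) -> List[str]:
    values: List[str] = []

    def visit(inst):
        if tuple(inst.path) == tuple(path) and inst.value is not None:
            values.append(inst.value)
        for child in inst.children:
            visit(child)

    for subject in clinical.subjects:
        for inst in subject.instances:
            visit(inst)
    return values
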