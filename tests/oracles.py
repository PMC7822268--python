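"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available
(exhaustive scan, hand summation, enumeration) without touching the
implementation path it checks.
"""

from __future__ import annotations

import itertools
from importlib import resources

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _encode(seq: str, n_code: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.empty(len(seq), dtype=np.int8)
    for ch, v in _CODE.items():
        out[arr == ord(ch)] = v if ch != "N" else n_code
    return out


def brute_force_hits(db, query: str, max_mm: int = 2):
    """Exhaustive Hamming scan of *query* over every window of every
    database sequence.  N never matches (distinct codes per side).

    *db* is a list of objects with transcript_id, gene_id, sequence.
    Returns a set of (transcript_id, offset, mismatches).
    """
    k = len(query)
    q = _encode(query, n_code=4)
    hits = set()
    for t in db:
        if len(t.sequence) < k:
            continue
        text = _encode(t.sequence, n_code=5)  # text N != query N
        windows = np.lib.stride_tricks.sliding_window_view(text, k)
        mm = (windows != q[None, :]).sum(axis=1)
        for off in np.flatnonzero(mm <= max_mm):
            hits.add((t.transcript_id, int(off), int(mm[off])))
    return hits


def brute_force_gene_summary(db, query: str, target_gene_id: str,
                             max_mm: int = 2) -> tuple[int, int, int]:
    """Distinct genes at their minimum mismatch level, target excluded."""
    gene_of = {t.transcript_id: t.gene_id for t in db}
    best: dict[str, int] = {}
    for tid, _off, mm in brute_force_hits(db, query, max_mm):
        gene = gene_of[tid]
        if gene == target_gene_id:
            continue
        best[gene] = min(best.get(gene, 99), mm)
    counts = [0, 0, 0]
    for mm in best.values():
        counts[mm] += 1
    return tuple(counts)


def nn_table(name: str) -> dict[str, tuple[float, float, float]]:
    """Re-parse a shipped nearest-neighbor TSV directly."""
    text = (
        resources.files("oligopipe.data").joinpath(f"nn_{name}.tsv").read_text()
    )
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("dimer"):
            continue
        key, dh, ds, dg = line.split("\t")
        table[key] = (float(dh), float(ds), float(dg))
    return table


def nn_dg_sum(seq: str, table: dict) -> float:
    """Hand summation of init + stacks + terminal terms over the table."""
    total = table.get("init", (0, 0, 0))[2]
    for i in range(len(seq) - 1):
        total += table[seq[i:i + 2]][2]
    for terminal in (seq[0], seq[-1]):
        key = "term_AT" if terminal in "AT" else "term_GC"
        if key in table:
            total += table[key][2]
    return total


def max_stem(seq: str, min_loop: int = 3) -> int:
    """Longest inverted-repeat stem by direct triple enumeration."""
    n = len(seq)
    best = 0
    for length in range(1, n // 2 + 1):
        for i in range(n - length + 1):
            for j in range(i + length + min_loop, n - length + 1):
                stem1 = seq[i:i + length]
                stem2 = seq[j:j + length]
                if all(_PAIR[a] == b
                       for a, b in zip(stem1, reversed(stem2))):
                    best = max(best, length)
    return best


def sirna_checklist(sense: str) -> int:
    """Independent application of the point-based siRNA rule list."""
    assert len(sense) == 19
    score = 0
    gc = 100.0 * sum(1 for b in sense if b in "GC") / 19
    if 30.0 <= gc <= 52.0:
        score += 1
    score += sum(1 for b in sense[14:] if b in "AT")
    if max_stem(sense, min_loop=3) < 4:
        score += 1
    if sense[18] == "A":
        score += 1
    if sense[2] == "A":
        score += 1
    if sense[9] == "T":
        score += 1
    if sense[18] in "GC":
        score -= 1
    if sense[12] == "G":
        score -= 1
    return max(score, 0)


def best_min_gap(starts: list[int], n_pick: int) -> int:
    """Brute-force optimal max-min pairwise gap over all n_pick subsets."""
    best = -1
    for combo in itertools.combinations(sorted(starts), n_pick):
        gap = min(b - a for a, b in zip(combo, combo[1:]))
        best = max(best, gap)
    return best
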