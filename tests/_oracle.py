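"""Independent brute-force in-silico-PCR oracle.

Expands each degenerate primer into all concrete A/C/G/T sequences and
slides every expansion over the template with exact byte equality; the
mismatch count at a site is the minimum Hamming distance over expansions.
Shares no matching code with the package's bitmask scanner.
"""

from __future__ import annotations

import itertools

import numpy as np

_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expansions(primer: str) -> list[str]:
    return ["".join(t) for t in itertools.product(*(_SETS[c] for c in primer.upper()))]


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def min_hamming_sites(primer: str, seq: str, max_mm: int) -> dict[int, int]:
    """Start -> min Hamming distance over all concrete expansions (<= max_mm)."""
    k = len(primer)
    if len(seq) < k:
        return {}
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    best = np.full(windows.shape[0], k + 1, dtype=np.int64)
    for exp in expansions(primer):
        e = np.frombuffer(exp.encode(), dtype=np.uint8)
        np.minimum(best, (windows != e).sum(axis=1), out=best)
    return {int(i): int(best[i]) for i in np.flatnonzero(best <= max_mm)}


def _pairings(fwd, rev, flen, rlen, max_amplicon):
    """Per forward site the shortest legal product; nested candidates dropped."""
    cands = []
    for s in sorted(fwd):
        legal = [
            r for r in sorted(rev)
            if r >= s + flen and (r + rlen - s) <= max_amplicon
        ]
        if legal:
            r = legal[0]
            cands.append((s, r + rlen, fwd[s], rev[r]))
    out = []
    for c in cands:
        nested = any(
            o[0] <= c[0] and c[1] <= o[1] and (o[0], o[1]) != (c[0], c[1]) for o in cands
        )
        if not nested:
            out.append(c)
    return out


def brute_force_amplicons(forward, reverse, seq, max_mm, max_amplicon):
    """All (strand, start, end, fwd_mm, rev_mm) tuples, plus-strand coords."""
    seq = seq.upper()
    L = len(seq)
    flen, rlen = len(forward), len(reverse)
    hits = []
    # plus strand: forward primer as-is, reverse primer's reverse complement
    fwd = min_hamming_sites(forward, seq, max_mm)
    rev = {}
    k = rlen
    if L >= k:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        best = np.full(windows.shape[0], k + 1, dtype=np.int64)
        for exp in expansions(reverse):
            e = np.frombuffer(revcomp(exp).encode(), dtype=np.uint8)
            np.minimum(best, (windows != e).sum(axis=1), out=best)
        rev = {int(i): int(best[i]) for i in np.flatnonzero(best <= max_mm)}
    for s, e, fm, rm in _pairings(fwd, rev, flen, rlen, max_amplicon):
        hits.append(("+", s, e, fm, rm))
    # minus strand: same scan on the reverse complement, coords mapped back
    rc = revcomp(seq)
    fwd_m = min_hamming_sites(forward, rc, max_mm)
    rev_m = {}
    if L >= k:
        arr = np.frombuffer(rc.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        best = np.full(windows.shape[0], k + 1, dtype=np.int64)
        for exp in expansions(reverse):
            e = np.frombuffer(revcomp(exp).encode(), dtype=np.uint8)
            np.minimum(best, (windows != e).sum(axis=1), out=best)
        rev_m = {int(i): int(best[i]) for i in np.flatnonzero(best <= max_mm)}
    for s, e, fm, rm in _pairings(fwd_m, rev_m, flen, rlen, max_amplicon):
        hits.append(("-", L - e, L - s, fm, rm))
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits
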