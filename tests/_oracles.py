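"""Independent brute-force oracles for the motif scanner.

These enumerate every matching substring directly from the pattern
definition (regex fullmatch per candidate (start, end) pair) and are
deliberately naive: they share no code with the production DP scanner.
"""

from __future__ import annotations

import re

from quadtract.motifs import SignatureSpec, merge_intervals


def brute_force_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Character-by-character maximal-run scan."""
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def brute_force_signature_sites(
    seq: str, base: str, spec: SignatureSpec
) -> list[tuple[int, int]]:
    """Union of every substring matching the signature, merged."""
    t, k = spec.min_tract_len, spec.n_tracts
    pat = re.compile(
        f"{base}{{{t},}}"
        f"(?:[ACGT]{{{spec.min_loop},{spec.max_loop}}}{base}{{{t},}}){{{k - 1}}}"
    )
    n = len(seq)
    head = base * t
    ivs = []
    for s in range(n - spec.min_span + 1):
        if seq[s : s + t] != head:
            continue
        for e in range(s + spec.min_span, n + 1):
            if seq[e - t : e] != head:
                continue
            if pat.fullmatch(seq, s, e):
                ivs.append((s, e))
    return merge_intervals(sorted(ivs))
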