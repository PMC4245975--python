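"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive site discovery from first principles (direct
reverse-complement window comparison), independent of the package's scanner
implementations.
"""

from __future__ import annotations

COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_canonical_sites(guide_seq: str, utr_seq: str, include_6mer: bool = False):
    """Slide every window and compare against the reverse complement directly.

    Returns (site_type, 1-based inclusive span) tuples, applying the
    8mer > 7mer-m8 > 7mer-A1 > 6mer precedence at each A1 anchor.
    """
    seed27 = guide_seq[1:7]
    seed28 = guide_seq[1:8]
    out = []
    n = len(utr_seq)
    for a in range(6, n + 1):  # anchor: 0-based index opposite guide position 1
        found = None
        if a >= 7 and a < n and utr_seq[a - 7 : a] == rc(seed28) and utr_seq[a] == "A":
            found = ("8mer", (a - 6, a + 1))
        elif a >= 7 and utr_seq[a - 7 : a] == rc(seed28):
            found = ("7mer-m8", (a - 6, a))
        elif a < n and utr_seq[a - 6 : a] == rc(seed27) and utr_seq[a] == "A":
            found = ("7mer-A1", (a - 5, a + 1))
        elif include_6mer and utr_seq[a - 6 : a] == rc(seed27):
            found = ("6mer", (a - 5, a))
        if found:
            out.append(found)
    return out


def naive_relaxed_sites(guide_seq: str, utr_seq: str, budgets: dict[int, tuple[int, int]]):
    """Enumerate all windows x all seed lengths, counting defects pair by pair.

    ``budgets`` maps seed length to (max_gu, max_mismatch).  Returns
    (seed_length, span, n_mm, n_gu) tuples.
    """
    out = []
    for L, (max_gu, max_mm) in sorted(budgets.items()):
        if len(guide_seq) < L + 1:
            continue
        seed = guide_seq[1 : L + 1]
        for start in range(len(utr_seq) - L + 1):
            window = utr_seq[start : start + L]
            n_gu = n_mm = 0
            for k in range(L):
                g, t = seed[k], window[L - 1 - k]
                if COMP[g] == t:
                    continue
                if {g, t} == {"G", "U"}:
                    n_gu += 1
                else:
                    n_mm += 1
            if n_gu <= max_gu and n_mm <= max_mm:
                out.append((L, (start + 1, start + L), n_mm, n_gu))
    return out


def naive_retarget_hits(seed: str, seq: str, max_mm: int):
    """All 6-nt windows within ``max_mm`` non-Watson-Crick oppositions."""
    out = []
    target = rc(seed)
    for start in range(len(seq) - 5):
        window = seq[start : start + 6]
        defects = [i for i in range(6) if window[i] != target[i]]
        if len(defects) <= max_mm:
            # defect at window index i opposes guide position 2 + (5 - i)
            positions = [2 + (5 - i) for i in defects]
            out.append(((start + 1, start + 6), len(defects), positions))
    return out
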