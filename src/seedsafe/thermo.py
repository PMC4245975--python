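"""Nearest-neighbor duplex energy, site accessibility and loading asymmetry.

The model is the Turner 2004 37 C nearest-neighbor parameter set, shipped as
versioned TSV data (stacks for Watson-Crick and G:U pairs, loop-size
initiation penalties, multiloop and misc terms).  Two dynamic programs are
implemented:

* ``duplex_energy`` — minimum free energy of a guide:target hybrid allowing
  mismatches and internal loops up to 3x3 and no multiloops (guide:target
  hybrids are short).  Single mismatches cost a flat, configurable penalty
  (default +1.0 kcal/mol); G:U is treated as a stacking pair.

* ``opening_energy`` — the accessibility cost of a target site, computed as
  the difference between the unconstrained MFE of the local window and the
  MFE with the site nucleotides forced unpaired (a simplified Zuker fold:
  stacks, size-dependent hairpin/bulge/internal penalties with a NINIO
  asymmetry term, affine multiloops; no terminal-mismatch or special-hairpin
  terms).

Sign conventions: more negative = more stable; dg_open <= 0 with 0 meaning a
fully accessible site; ddg = dg_duplex - dg_open, so inaccessible sites are
penalized and lower ddg means a stronger site.  ddg below the functional
threshold (default -10 kcal/mol) flags a site as likely functional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit

from .seqcore import COMPLEMENT, Guide, SeedsafeError

_INF = 1 << 28
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair-type indices matching the stack-table row/column order
_PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
_PT = np.full((4, 4), -1, dtype=np.int64)
for _k, _p in enumerate(_PAIR_ORDER):
    _PT[_NT_INDEX[_p[0]], _NT_INDEX[_p[1]]] = _k

DEFAULT_FLANK = 50
DEFAULT_FUNCTIONAL_THRESHOLD = -10.0  # kcal/mol
DEFAULT_MISMATCH_PENALTY = 1.0  # kcal/mol per internal 1x1 mismatch
DEFAULT_K_TERMINAL = 4
_MAXLOOP = 30


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as int64 indices (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([_NT_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise SeedsafeError(f"invalid nucleotide {exc.args[0]!r}") from None


@dataclass(frozen=True)
class EnergyModel:
    """Versioned nearest-neighbor energy tables (dcal/mol internally)."""

    stack: np.ndarray          # 6x6, folding-matrix convention
    hairpin: np.ndarray        # size 0..30
    bulge: np.ndarray
    internal: np.ndarray
    duplex_init: int
    terminal_au: int
    ml_closing: int
    ml_branch: int
    ml_unpaired: int
    ninio_per_nt: int
    ninio_max: int
    lxc: float
    mismatch_penalty: int = 100
    version: str = "turner2004-37C"

    def pair_stack(self, doublet_top: str, doublet_bottom: str) -> float:
        """ΔG (kcal/mol) of the step 5'-xy-3' / 3'-x'y'-5'.

        ``doublet_top`` = xy, ``doublet_bottom`` = x'y' (3'->5').  Raises for
        non-pairing combinations.
        """
        x, y = (_NT_INDEX[c] for c in doublet_top)
        xp, yp = (_NT_INDEX[c] for c in doublet_bottom)
        t1, t2 = _PT[x, xp], _PT[yp, y]
        if t1 < 0 or t2 < 0:
            raise SeedsafeError(
                f"non-pairing doublet {doublet_top}/{doublet_bottom}"
            )
        return float(self.stack[t1, t2]) / 100.0


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("seedsafe.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


_MODEL_CACHE: dict[float, EnergyModel] = {}


def load_energy_model(mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY) -> EnergyModel:
    """Load the shipped Turner 2004 tables into an EnergyModel."""
    if mismatch_penalty in _MODEL_CACHE:
        return _MODEL_CACHE[mismatch_penalty]
    rows = _read_table("nn_stacks_turner2004.tsv")
    header = rows[0][1:]
    if tuple(header) != _PAIR_ORDER:
        raise SeedsafeError("stack table column order does not match pair order")
    stack = np.full((6, 6), _INF, dtype=np.int64)
    for row in rows[1:]:
        i = _PAIR_ORDER.index(row[0])
        for j, v in enumerate(row[1:]):
            stack[i, j] = int(v)

    loops = _read_table("loop_penalties_turner2004.tsv")
    hairpin = np.full(31, _INF, dtype=np.int64)
    bulge = np.full(31, _INF, dtype=np.int64)
    internal = np.full(31, _INF, dtype=np.int64)
    for row in loops[1:]:
        size = int(row[0])
        for arr, v in zip((hairpin, bulge, internal), row[1:]):
            arr[size] = _INF if v == "inf" else int(v)

    misc = {row[0]: float(row[1]) for row in _read_table("misc_energies_turner2004.tsv")[1:]}
    model = EnergyModel(
        stack=stack,
        hairpin=hairpin,
        bulge=bulge,
        internal=internal,
        duplex_init=int(misc["duplex_init"]),
        terminal_au=int(misc["terminal_au"]),
        ml_closing=int(misc["ml_closing"]),
        ml_branch=int(misc["ml_branch"]),
        ml_unpaired=int(misc["ml_unpaired"]),
        ninio_per_nt=int(misc["ninio_per_nt"]),
        ninio_max=int(misc["ninio_max"]),
        lxc=misc["lxc"],
        mismatch_penalty=int(round(mismatch_penalty * 100)),
    )
    _MODEL_CACHE[mismatch_penalty] = model
    return model


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _loop_size_energy(tab, size, lxc):
    if size <= 30:
        return tab[size]
    return tab[30] + np.int64(lxc * math.log(size / 30.0))


@njit(cache=False)
def _fold_mfe(seq, mask, stack, hairpin, bulge, internal,
              ml_closing, ml_branch, ml_unpaired,
              ninio_per_nt, ninio_max, lxc, pt):
    """Simplified Zuker MFE (dcal/mol) of one window; masked positions stay unpaired."""
    n = seq.shape[0]
    INF = _INF
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    WM2 = np.full((n, n), INF, dtype=np.int64)
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            tij = pt[seq[i], seq[j]]
            if tij >= 0 and not mask[i] and not mask[j]:
                best = _loop_size_energy(hairpin, j - i - 1, lxc)
                # stacks, bulges, internal loops (bounded size)
                for p in range(i + 1, min(i + _MAXLOOP + 1, j - 4) + 1):
                    l1 = p - i - 1
                    qmin = max(p + 4, j - 1 - (_MAXLOOP - l1))
                    for q in range(qmin, j):
                        if V[p, q] >= INF:
                            continue
                        l2 = j - q - 1
                        if l1 == 0 and l2 == 0:
                            s = stack[tij, pt[seq[j - 1], seq[i + 1]]]
                            if s >= INF:
                                continue
                            e = s + V[p, q]
                        elif l1 == 0 or l2 == 0:
                            size = l1 + l2
                            e = _loop_size_energy(bulge, size, lxc) + V[p, q]
                            if size == 1:
                                s = stack[tij, pt[seq[q], seq[p]]]
                                if s < INF:
                                    e += s
                        else:
                            size = l1 + l2
                            asym = l1 - l2 if l1 > l2 else l2 - l1
                            pen = ninio_per_nt * asym
                            if pen > ninio_max:
                                pen = ninio_max
                            e = _loop_size_energy(internal, size, lxc) + pen + V[p, q]
                        if e < best:
                            best = e
                # multiloop closing
                if WM2[i + 1, j - 1] < INF:
                    e = ml_closing + ml_branch + WM2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # WM / WM2 (multiloop interior segments)
            w = INF
            if V[i, j] < INF:
                w = V[i, j] + ml_branch
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_unpaired
                if e < w:
                    w = e
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_unpaired
                if e < w:
                    w = e
            w2 = INF
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < w2:
                        w2 = e
            if w2 < w:
                w = w2
            WM[i, j] = w
            WM2[i, j] = w2
    # exterior loop
    W = np.zeros(n, dtype=np.int64)
    for j in range(n):
        w = W[j - 1] if j > 0 else 0
        for i in range(0, j - 3):
            if V[i, j] < INF:
                e = (W[i - 1] if i > 0 else 0) + V[i, j]
                if e < w:
                    w = e
        W[j] = w
    mfe = W[n - 1] if n > 0 else 0
    return mfe if mfe < 0 else 0


@njit(cache=False)
def _duplex_mfe(g, t, stack, internal, mismatch_penalty, terminal_au,
                ninio_per_nt, ninio_max, lxc, pt):
    """Min free energy (dcal/mol, no init term) of a guide:target hybrid.

    Guide and target are both 5'->3'; pairing is antiparallel.  Internal
    loops up to 3x3; 1x1 loops cost the flat mismatch penalty.
    """
    m = g.shape[0]
    n = t.shape[0]
    INF = _INF
    D = np.full((m, n), INF, dtype=np.int64)
    best = INF
    for i in range(m):
        for j in range(n - 1, -1, -1):
            tp = pt[g[i], t[j]]
            if tp < 0:
                continue
            au = terminal_au if (tp >= 2) else 0  # GU/UG/AU/UA termini
            e = au  # start a new duplex at this pair
            for pi in range(max(0, i - 4), i):
                l1 = i - pi - 1
                for pj in range(j + 1, min(n, j + 5)):
                    if D[pi, pj] >= INF:
                        continue
                    l2 = pj - j - 1
                    if l1 > 3 or l2 > 3:
                        continue
                    if l1 == 0 and l2 == 0:
                        s = stack[pt[g[pi], t[pj]], pt[t[j], g[i]]]
                        if s >= INF:
                            continue
                        cost = s
                    elif l1 == 1 and l2 == 1:
                        cost = mismatch_penalty
                    else:
                        size = l1 + l2
                        asym = l1 - l2 if l1 > l2 else l2 - l1
                        pen = ninio_per_nt * asym
                        if pen > ninio_max:
                            pen = ninio_max
                        cost = _loop_size_energy(internal, size, lxc) + pen
                    cand = D[pi, pj] + cost
                    if cand < e:
                        e = cand
            D[i, j] = e
            close = e + au
            if close < best:
                best = close
    if best >= INF:
        return 0
    return best if best < 0 else 0


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def duplex_energy(
    guide: Guide | str,
    target_window: str,
    model: EnergyModel | None = None,
    include_init: bool = False,
) -> float:
    """MFE (kcal/mol) of the guide:target hybrid; more negative = more stable.

    The duplex-initiation constant is excluded by default (it cancels in every
    ΔΔG comparison); ``include_init=True`` adds it for comparison against
    free-energy oracles.  Returns 0.0 when no stable hybrid can form
    (including the degenerate case of a strand too short to stack).
    """
    model = model or load_energy_model()
    gseq = guide.sequence if isinstance(guide, Guide) else guide
    if min(len(gseq), len(target_window)) < 2:
        return 0.0
    if len(target_window) < 6:
        raise SeedsafeError(f"target window shorter than 6 nt: {target_window!r}")
    e = _duplex_mfe(
        encode(gseq), encode(target_window),
        model.stack, model.internal, model.mismatch_penalty, model.terminal_au,
        model.ninio_per_nt, model.ninio_max, model.lxc, _PT,
    )
    e = float(e)
    if include_init and e < 0:
        e += model.duplex_init
    return min(e, 0.0) / 100.0 if not include_init else e / 100.0


def window_mfe(sequence: str, constrained_unpaired: tuple[int, int] | None = None,
               model: EnergyModel | None = None) -> float:
    """MFE (kcal/mol) of a window, optionally with a 1-based span forced unpaired."""
    model = model or load_energy_model()
    seq = encode(sequence)
    mask = np.zeros(len(seq), dtype=np.bool_)
    if constrained_unpaired is not None:
        a, b = constrained_unpaired
        if not (1 <= a <= b <= len(seq)):
            raise SeedsafeError(f"constraint span {constrained_unpaired} outside window")
        mask[a - 1 : b] = True
    e = _fold_mfe(
        seq, mask, model.stack, model.hairpin, model.bulge, model.internal,
        model.ml_closing, model.ml_branch, model.ml_unpaired,
        model.ninio_per_nt, model.ninio_max, model.lxc, _PT,
    )
    return float(e) / 100.0


def opening_energy(
    utr_sequence: str,
    site_span: tuple[int, int],
    flank: int = DEFAULT_FLANK,
    model: EnergyModel | None = None,
) -> float:
    """Accessibility cost ΔGopen (kcal/mol) of a site inside its local window.

    dg_open = MFE(window, unconstrained) - MFE(window, site forced unpaired);
    by construction <= 0, with 0 meaning a fully accessible site.
    """
    model = model or load_energy_model()
    s, e = site_span
    if not (1 <= s <= e <= len(utr_sequence)):
        raise SeedsafeError(f"site span {site_span} outside sequence")
    if flank < 0:
        raise SeedsafeError("flank must be >= 0")
    w_start = max(0, s - 1 - flank)
    w_end = min(len(utr_sequence), e + flank)
    window = utr_sequence[w_start:w_end]
    local = (s - w_start, e - w_start)
    g_free = window_mfe(window, None, model)
    g_constrained = window_mfe(window, local, model)
    return min(g_free - g_constrained, 0.0)


@dataclass(frozen=True)
class DdgScore:
    """ΔGduplex, ΔGopen and their difference for one site."""

    dg_duplex: float
    dg_open: float
    ddg: float
    likely_functional: bool


def ddg(dg_duplex: float, dg_open: float,
        functional_threshold: float = DEFAULT_FUNCTIONAL_THRESHOLD) -> DdgScore:
    """Combine hybridization and accessibility into the site-strength score.

    ddg = dg_duplex - dg_open.  Sites with ddg below the functional threshold
    (default -10 kcal/mol) are flagged as likely functional.
    """
    if not (math.isfinite(dg_duplex) and math.isfinite(dg_open)):
        raise SeedsafeError("non-finite energy input")
    value = dg_duplex - dg_open
    return DdgScore(dg_duplex, dg_open, value, value < functional_threshold)


def duplex_window_span(site_span: tuple[int, int], guide_length: int,
                       seq_length: int, extra: int = 2) -> tuple[int, int]:
    """1-based window on the target that the full guide can pair with.

    The guide 5' end sits at the site 3' end, so the window extends upstream
    (5' on the target) far enough for the guide 3' region plus a small bulge
    allowance.
    """
    s, e = site_span
    return (max(1, e - guide_length - extra + 1), e)


def site_ddg(guide: Guide, utr_sequence: str, site_span: tuple[int, int],
             flank: int = DEFAULT_FLANK, model: EnergyModel | None = None,
             functional_threshold: float = DEFAULT_FUNCTIONAL_THRESHOLD) -> DdgScore:
    """Full ΔΔG score of one guide site on a UTR sequence."""
    model = model or load_energy_model()
    ws, we = duplex_window_span(site_span, len(guide), len(utr_sequence))
    window = utr_sequence[ws - 1 : we]
    dgd = duplex_energy(guide, window, model)
    dgo = opening_energy(utr_sequence, site_span, flank, model)
    return ddg(dgd, dgo, functional_threshold)


def asymmetry_score(guide: Guide | str, passenger: str, k: int = DEFAULT_K_TERMINAL,
                    model: EnergyModel | None = None) -> float:
    """5'-end thermodynamic asymmetry of a guide:passenger duplex (kcal/mol).

    The strands are assumed fully paired in antiparallel register (guide 5'
    end opposite passenger 3' end).  The score is the stacking stability of
    the k terminal pairs at the guide 5' end minus that at the passenger 5'
    end; a positive score (guide end less stable) predicts guide-strand
    loading into RISC.  Non-pairing steps contribute no stack.
    """
    model = model or load_energy_model()
    gseq = guide.sequence if isinstance(guide, Guide) else guide
    pseq = passenger
    n = min(len(gseq), len(pseq))
    if k > n:
        raise SeedsafeError(f"k={k} exceeds duplex length {n}")
    if k == 0:
        return 0.0

    def end_stability(top: str, bottom: str) -> float:
        # top 5'->3' terminal k nts pairing bottom 3'->5' terminal k nts
        total = 0.0
        for i in range(k - 1):
            a, b = top[i], top[i + 1]
            ap, bp = bottom[-(i + 1)], bottom[-(i + 2)]
            t1 = _PT[_NT_INDEX[a], _NT_INDEX[ap]]
            t2 = _PT[_NT_INDEX[bp], _NT_INDEX[b]]
            if t1 >= 0 and t2 >= 0:
                total += float(model.stack[t1, t2]) / 100.0
        return total

    guide5 = end_stability(gseq, pseq)
    passenger5 = end_stability(pseq, gseq)
    return guide5 - passenger5
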