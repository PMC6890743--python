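"""RNA secondary-structure thermodynamics engine.

Implements minimum-free-energy (MFE) folding, a complete exhaustive-enumeration
oracle for short sequences, a McCaskill-style partition function with
base-pair probabilities, ensemble statistics (normalized Shannon entropy NQ,
normalized base-pair distance ND), hairpin screening descriptors
(AMFE, MFEI, Npb), and intermolecular duplex scoring.

The energy model is a deliberately simple nearest-neighbour stacking model:
every allowed pair (AU, UA, GC, CG, GU, UG) carries a "bond strength"
b(x,y) > 0 and two coaxially stacked pairs (i,j),(i+1,j-1) contribute
``-(b1 + b2) / 2`` model units (kcal/mol-like).  Unpaired bases, loops and
isolated pairs are energy-neutral.  This keeps the model self-contained and
exactly checkable against structure enumeration while preserving the
behaviour the screening indices (AMFE, MFEI, NQ, ND, Npb) rely on: GC-rich,
well-stacked hairpins fold deep and sharp, shuffled sequences fold shallow
and diffuse.  An external ViennaRNA backend can substitute the MFE fold
(see :func:`fold_mfe_rnafold`).
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "EnsembleStats",
    "HairpinDescriptors",
    "DuplexResult",
    "encode_sequence",
    "fold_mfe",
    "fold_mfe_rnafold",
    "enumerate_structures",
    "count_structures",
    "structure_energy",
    "partition_function",
    "ensemble_stats_from_probs",
    "hairpin_descriptors",
    "duplex_score",
    "duplex_bruteforce",
]

_ALPHA = "ACGU"
_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_INF = 1e30


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 (A=0, C=1, G=2, U/T=3).

    Raises ``ValueError`` on any other character.
    """
    try:
        return np.array([_IDX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"invalid nucleotide {e.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """Stacking energy model.

    ``bond`` is a symmetric 4x4 table of bond strengths; entry 0 means the
    pair is disallowed.  The stack energy of two adjacent pairs is
    ``-(bond[p1] + bond[p2]) / 2``, which is symmetric under duplex reversal
    by construction.  ``kT`` is the Boltzmann temperature scale used by the
    partition function (model units).
    """

    bond: np.ndarray = field(
        default_factory=lambda: _default_bond_table()
    )
    min_hairpin_loop: int = 3
    kT: float = 0.6

    def __post_init__(self):
        b = np.asarray(self.bond, dtype=np.float64)
        if b.shape != (4, 4) or not np.allclose(b, b.T):
            raise ValueError("bond table must be a symmetric 4x4 matrix")
        object.__setattr__(self, "bond", b)

    def allowed(self, x: int, y: int) -> bool:
        return self.bond[x, y] > 0


def _default_bond_table() -> np.ndarray:
    b = np.zeros((4, 4))
    A, C, G, U = 0, 1, 2, 3
    b[A, U] = b[U, A] = 2.1
    b[G, C] = b[C, G] = 3.3
    b[G, U] = b[U, G] = 1.4
    return b


DEFAULT_MODEL = EnergyModel()


@dataclass
class SecondaryStructure:
    """A nested secondary structure: dot-bracket string, pair list, MFE."""

    sequence: str
    dot_bracket: str
    pairs: list  # list of (i, j), 0-based, i < j
    mfe: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


@dataclass
class EnsembleStats:
    """Boltzmann-ensemble quantities of a sequence under the model."""

    Z: float
    log_Z: float
    p: np.ndarray  # p[i, j] = probability that i pairs j (upper triangle)
    NQ: float  # normalized Shannon entropy of the pairing distribution
    ND: float  # normalized base-pair distance


@dataclass
class HairpinDescriptors:
    """Pre-miRNA screening descriptors of a folded window."""

    length: int
    gc_pct: float
    au_pct: float
    amfe: float  # (|MFE| / L) * 100
    mfei: float  # AMFE / GC%
    npb: float  # base pairs in the MFE structure / L
    r: float | None = None  # SSR signature score, attached by the caller
    mfei_defined: bool = True  # False when GC% == 0 (candidate rejected)


# ---------------------------------------------------------------------------
# MFE folding (Zuker-style DP over stacks)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_mfe(enc, bond, minloop):
    n = enc.size
    W = np.zeros((n, n))
    Wno = np.zeros((n, n))
    V = np.full((n, n), _INF)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            # V: (i, j) paired
            if bond[enc[i], enc[j]] > 0 and j - i - 1 >= minloop:
                a, b = i + 1, j - 1
                best = Wno[a, b] if b > a else 0.0
                if (
                    b - a - 1 >= minloop
                    and bond[enc[a], enc[b]] > 0
                    and V[a, b] < _INF
                ):
                    st = -(bond[enc[i], enc[j]] + bond[enc[a], enc[b]]) / 2.0
                    if st + V[a, b] < best:
                        best = st + V[a, b]
                V[i, j] = best
            # W / Wno: decompose by the status of j
            w = W[i, j - 1]  # j unpaired
            wno = w
            for k in range(i, j - minloop):
                if V[k, j] < _INF:
                    left = W[i, k - 1] if k > i else 0.0
                    cand = left + V[k, j]
                    if cand < w:
                        w = cand
                    if k > i and cand < wno:
                        wno = cand
            W[i, j] = w
            Wno[i, j] = wno
    return W, Wno, V


def _stack_energy(enc, bond, i, j, a, b):
    return -(bond[enc[i], enc[j]] + bond[enc[a], enc[b]]) / 2.0


def fold_mfe(sequence: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Fold to the minimum-free-energy nested structure.

    Deterministic traceback; on exact energy ties the branch with fewer
    pairs is preferred, so energy-neutral isolated pairs never appear in
    the reported structure.
    """
    model = model or DEFAULT_MODEL
    enc = encode_sequence(sequence)
    n = enc.size
    if n == 0:
        raise ValueError("empty sequence")
    ml = model.min_hairpin_loop
    if n < ml + 2:
        return SecondaryStructure(sequence, "." * n, [], 0.0)
    W, Wno, V = _fill_mfe(enc, model.bond, ml)
    bond = model.bond
    pairs: list = []

    def wval(i, j):
        return 0.0 if j < i else (0.0 if i == j else W[i, j])

    def wnoval(i, j):
        return 0.0 if j <= i else Wno[i, j]

    stack_frames = [("W", 0, n - 1)]
    while stack_frames:
        mode, i, j = stack_frames.pop()
        if j <= i:
            continue
        if mode == "V":
            pairs.append((i, j))
            a, b = i + 1, j - 1
            target = V[i, j]
            if target == wnoval(a, b):
                stack_frames.append(("Wno", a, b))
            else:
                st = _stack_energy(enc, bond, i, j, a, b)
                assert V[a, b] < _INF and target == st + V[a, b]
                stack_frames.append(("V", a, b))
            continue
        target = W[i, j] if mode == "W" else Wno[i, j]
        if target == wval(i, j - 1):
            stack_frames.append(("W", i, j - 1))
            continue
        k0 = i if mode == "W" else i + 1
        done = False
        for k in range(k0, j - ml):
            if V[k, j] < _INF:
                left = wval(i, k - 1)
                if target == left + V[k, j]:
                    stack_frames.append(("V", k, j))
                    if k > i:
                        stack_frames.append(("W", i, k - 1))
                    done = True
                    break
        assert done, "traceback failed"

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return SecondaryStructure(sequence, "".join(db), pairs, float(W[0, n - 1]))


def fold_mfe_rnafold(sequence: str) -> SecondaryStructure:
    """MFE fold via the external RNAfold program (ViennaRNA backend).

    Energies are on the Turner-parameter kcal/mol scale, not the internal
    model scale; use for decision-level comparisons only.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"],
        input=sequence + "\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split()[0]
    energy = float(struct_line[struct_line.rindex("(") + 1 : struct_line.rindex(")")])
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    return SecondaryStructure(sequence, db, sorted(pairs), energy)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------


def structure_energy(enc: np.ndarray, pairs, model: EnergyModel) -> float:
    """Energy of an explicit pair set: sum of coaxial stack terms."""
    pset = set(pairs)
    e = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pset:
            e += _stack_energy(enc, model.bond, i, j, i + 1, j - 1)
    return e


def enumerate_structures(
    sequence: str, model: EnergyModel | None = None, cap: int = 22
):
    """Enumerate every valid nested structure with its energy.

    Complete, non-redundant enumeration (decomposition by the pairing status
    of the interval's right end).  Ground-truth oracle for folding and the
    partition function; refuses sequences longer than ``cap``.
    """
    model = model or DEFAULT_MODEL
    enc = encode_sequence(sequence)
    n = enc.size
    if n > cap:
        raise ValueError(f"sequence length {n} above enumeration cap {cap}")
    ml = model.min_hairpin_loop
    bond = model.bond
    memo: dict = {}

    def rec(i, j):
        if j - i < ml + 1:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [s for s in rec(i, j - 1)]
        for k in range(i, j - ml):
            if bond[enc[k], enc[j]] > 0:
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        memo[key] = out
        return out

    return [
        (tuple(sorted(s)), structure_energy(enc, s, model)) for s in rec(0, n - 1)
    ]


def count_structures(sequence: str, model: EnergyModel | None = None) -> int:
    """Count valid nested structures by direct recursion.

    Independent of :func:`enumerate_structures` (counts without
    materializing), used to cross-check the enumeration.
    """
    model = model or DEFAULT_MODEL
    enc = encode_sequence(sequence)
    n = enc.size
    ml = model.min_hairpin_loop
    bond = model.bond
    memo: dict = {}

    def rec(i, j):
        if j - i < ml + 1:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = rec(i, j - 1)
        for k in range(i, j - ml):
            if bond[enc[k], enc[j]] > 0:
                total += rec(i, k - 1) * rec(k + 1, j - 1)
        memo[(i, j)] = total
        return total

    return rec(0, n - 1)


# ---------------------------------------------------------------------------
# Partition function (inside/outside)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_inside(enc, bond, minloop, beta, sigma):
    n = enc.size
    Q = np.zeros((n, n))
    Qb = np.zeros((n, n))
    # Q over single bases
    for i in range(n):
        Q[i, i] = sigma
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            # Qb
            if bond[enc[i], enc[j]] > 0 and j - i - 1 >= minloop:
                a, b = i + 1, j - 1
                if b < a:
                    inner_no = 1.0
                elif b == a:
                    inner_no = sigma
                else:
                    inner_no = Q[a, b] - Qb[a, b]
                acc = inner_no
                if b > a and Qb[a, b] > 0:
                    st = -(bond[enc[i], enc[j]] + bond[enc[a], enc[b]]) / 2.0
                    acc += math.exp(-beta * st) * Qb[a, b]
                Qb[i, j] = sigma * sigma * acc
            # Q
            total = sigma * Q[i, j - 1]
            for k in range(i, j - minloop):
                if Qb[k, j] > 0:
                    left = Q[i, k - 1] if k > i else 1.0
                    total += left * Qb[k, j]
            Q[i, j] = total
    return Q, Qb


@njit(cache=True)
def _fill_outside(enc, bond, minloop, beta, sigma, Q, Qb):
    n = enc.size
    O = np.zeros((n, n))
    s2 = sigma * sigma
    # iterate spans from largest to smallest
    for d in range(n - 1, minloop, -1):
        for i in range(0, n - d):
            j = i + d
            if Qb[i, j] <= 0:
                continue
            left = Q[0, i - 1] if i > 0 else 1.0
            right = Q[j + 1, n - 1] if j < n - 1 else 1.0
            acc = left * right
            for k in range(0, i):
                for l in range(j + 1, n):
                    if Qb[k, l] > 0 and O[k, l] > 0:
                        if k == i - 1 and l == j + 1:
                            st = -(
                                bond[enc[k], enc[l]] + bond[enc[i], enc[j]]
                            ) / 2.0
                            acc += O[k, l] * s2 * math.exp(-beta * st)
                        else:
                            ql = Q[k + 1, i - 1] if i - 1 >= k + 1 else 1.0
                            qr = Q[j + 1, l - 1] if l - 1 >= j + 1 else 1.0
                            acc += O[k, l] * s2 * ql * qr
            O[i, j] = acc
    P = np.zeros((n, n))
    Z = Q[0, n - 1]
    for i in range(n):
        for j in range(i + 1, n):
            if Qb[i, j] > 0:
                P[i, j] = Qb[i, j] * O[i, j] / Z
    return P


def ensemble_stats_from_probs(p: np.ndarray, length: int) -> tuple:
    """(NQ, ND) from a base-pair probability matrix.

    NQ = -(1/L) * sum_{i<j} p_ij * log2(p_ij); ND = (1/L) * sum p_ij (1 - p_ij).
    """
    iu = np.triu_indices(p.shape[0], k=1)
    vals = p[iu]
    vals = vals[vals > 0]
    nq = float(-(vals * np.log2(vals)).sum() / length) if vals.size else 0.0
    nd = float((vals * (1.0 - vals)).sum() / length)
    return nq, nd


def partition_function(
    sequence: str, model: EnergyModel | None = None
) -> EnsembleStats:
    """McCaskill-style partition function and base-pair probabilities.

    The inside recursion is scaled per-nucleotide to avoid overflow on long
    windows; Z is reported unscaled (and as log Z, always finite).
    """
    model = model or DEFAULT_MODEL
    enc = encode_sequence(sequence)
    n = enc.size
    if n == 0:
        raise ValueError("empty sequence")
    beta = 1.0 / model.kT
    sigma = math.exp(-beta * model.bond.max() / 2.0)
    if n < model.min_hairpin_loop + 2:
        p = np.zeros((n, n))
        return EnsembleStats(1.0, 0.0, p, 0.0, 0.0)
    Q, Qb = _fill_inside(enc, model.bond, model.min_hairpin_loop, beta, sigma)
    P = _fill_outside(enc, model.bond, model.min_hairpin_loop, beta, sigma, Q, Qb)
    log_z = math.log(Q[0, n - 1]) - n * math.log(sigma)
    z = math.exp(log_z) if log_z < 700 else math.inf
    nq, nd = ensemble_stats_from_probs(P, n)
    return EnsembleStats(z, log_z, P, nq, nd)


# ---------------------------------------------------------------------------
# Hairpin descriptors
# ---------------------------------------------------------------------------


def composition_pct(sequence: str) -> tuple:
    """(gc_pct, au_pct) on the 0-100 scale over A/C/G/U(T) characters."""
    s = sequence.upper().replace("T", "U")
    n = sum(s.count(c) for c in _ALPHA)
    if n == 0:
        return 0.0, 0.0
    gc = (s.count("G") + s.count("C")) / n * 100.0
    au = (s.count("A") + s.count("U")) / n * 100.0
    return gc, au


def hairpin_descriptors(
    structure: SecondaryStructure, r: float | None = None
) -> HairpinDescriptors:
    """Screening descriptors of a folded window.

    AMFE = (|MFE|/L)*100, MFEI = AMFE / GC% (GC on the 0-100 scale), Npb =
    pairs in the MFE structure / L.  A GC-free window leaves MFEI undefined;
    the descriptor block is flagged and downstream screens reject it.
    """
    L = len(structure.sequence)
    gc, au = composition_pct(structure.sequence)
    amfe = abs(structure.mfe) / L * 100.0
    if gc == 0.0:
        return HairpinDescriptors(L, gc, au, amfe, 0.0, len(structure.pairs) / L,
                                  r, mfei_defined=False)
    return HairpinDescriptors(
        L, gc, au, amfe, amfe / gc, len(structure.pairs) / L, r
    )


# ---------------------------------------------------------------------------
# Intermolecular duplex scoring
# ---------------------------------------------------------------------------


@dataclass
class DuplexResult:
    """Best intermolecular duplex: energy and the pair list (i in a, j in b)."""

    energy: float
    pairs: list


@njit(cache=True)
def _fill_duplex(ea, eb, bond, loop_penalty, max_loop):
    n, m = ea.size, eb.size
    B = np.full((n, m), _INF)
    for i in range(n):
        for j in range(m):
            if bond[ea[i], eb[j]] <= 0:
                continue
            best = 0.0  # duplex starting at this pair
            for di in range(1, max_loop + 2):
                ip = i - di
                if ip < 0:
                    break
                for dj in range(1, max_loop + 2):
                    jp = j + dj
                    if jp >= m:
                        break
                    if B[ip, jp] >= _INF:
                        continue
                    if di == 1 and dj == 1:
                        st = -(bond[ea[ip], eb[jp]] + bond[ea[i], eb[j]]) / 2.0
                        cand = B[ip, jp] + st
                    else:
                        cand = B[ip, jp] + loop_penalty * ((di - 1) + (dj - 1))
                    if cand < best:
                        best = cand
            B[i, j] = best
    return B


def duplex_score(
    seq_a: str,
    seq_b: str,
    model: EnergyModel | None = None,
    loop_penalty: float = 0.5,
    max_loop: int = 8,
) -> DuplexResult:
    """Best antiparallel intermolecular hybridization energy.

    Both sequences are given 5'->3'; pairing is (i, j) with i advancing in
    ``seq_a`` while j recedes in ``seq_b``.  Stacks are scored by the model;
    interior loops/bulges cost ``loop_penalty`` per unpaired nucleotide
    (capped at ``max_loop`` per side); no intramolecular pairs.  A sequence
    pair with no allowed base pair scores 0.
    """
    model = model or DEFAULT_MODEL
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    ea, eb = encode_sequence(seq_a), encode_sequence(seq_b)
    B = _fill_duplex(ea, eb, model.bond, loop_penalty, max_loop)
    finite = B < _INF
    if not finite.any():
        return DuplexResult(0.0, [])
    best = float(B[finite].min())
    i, j = map(int, np.argwhere((B == best) & finite)[0])
    # traceback
    pairs = [(i, j)]
    bond = model.bond
    while B[i, j] != 0.0:
        found = False
        for di in range(1, max_loop + 2):
            ip = i - di
            if ip < 0:
                break
            for dj in range(1, max_loop + 2):
                jp = j + dj
                if jp >= eb.size or B[ip, jp] >= _INF:
                    continue
                if di == 1 and dj == 1:
                    cost = -(bond[ea[ip], eb[jp]] + bond[ea[i], eb[j]]) / 2.0
                else:
                    cost = loop_penalty * ((di - 1) + (dj - 1))
                if B[i, j] == B[ip, jp] + cost:
                    pairs.append((ip, jp))
                    i, j = ip, jp
                    found = True
                    break
            if found:
                break
        assert found, "duplex traceback failed"
    pairs.sort()
    return DuplexResult(best, pairs)


def duplex_bruteforce(
    seq_a: str,
    seq_b: str,
    model: EnergyModel | None = None,
    loop_penalty: float = 0.5,
    max_loop: int = 8,
) -> float:
    """Exhaustive search over all antiparallel pair chains (short inputs).

    Independent oracle for :func:`duplex_score`.
    """
    model = model or DEFAULT_MODEL
    ea, eb = encode_sequence(seq_a), encode_sequence(seq_b)
    n, m = ea.size, eb.size
    if n * m > 400:
        raise ValueError("input too long for brute-force duplex search")
    bond = model.bond
    best = [0.0]

    def rec(i, j, energy):
        # last pair is (i, j); try to extend
        if energy < best[0]:
            best[0] = energy
        for ip in range(i + 1, min(n, i + max_loop + 2)):
            for jp in range(max(-1, j - max_loop - 2) + 1, j):
                if bond[ea[ip], eb[jp]] <= 0:
                    continue
                if ip == i + 1 and jp == j - 1:
                    cost = -(bond[ea[i], eb[j]] + bond[ea[ip], eb[jp]]) / 2.0
                else:
                    cost = loop_penalty * ((ip - i - 1) + (j - jp - 1))
                rec(ip, jp, energy + cost)

    for i in range(n):
        for j in range(m):
            if bond[ea[i], eb[j]] > 0:
                rec(i, j, 0.0)
    return best[0]
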