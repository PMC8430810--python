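"""RNA secondary-structure prediction under a simplified loop-based model.

The minimum free energy (MFE) of an mRNA's secondary structure, normalized
by length, is the statistic this package uses to explain structure-dependent
dropout. Literature-comparable kcal/mol values come from an external
Turner-parameter engine (``fold_external``, an RNAfold adapter); the
internal model here is deliberately simple so that the Zuker-style dynamic
program can be verified *exactly* against exhaustive enumeration:

* allowed pairs: AU/UA, CG/GC, GU/UG; minimum hairpin loop 3 nt
* stack energy from the weaker of the two closing pairs:
  both CG/GC -> -3.0; any AU/UA -> -2.0; any GU/UG -> -1.0 kcal/mol
* hairpin loop of length l:     3.0 + 1.75 ln(l/3)
* internal/bulge, u unpaired:   2.0 + 1.75 ln(u)   (u >= 1)
* multiloop, affine:            3.4 + 0.4 per branching helix
                                (closing helix included), 0.0 per unpaired
* no dangles, no coaxial stacking, lonely pairs permitted

The DP is O(L^3) time / O(L^2) memory (internal loops capped at 30
unpaired nucleotides, the standard Zuker-implementation convention) and is
compiled with numba so full-length mRNAs (thousands of nt) fold in seconds.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import GeneRecord, ValidationError

__all__ = [
    "EnergyModel",
    "FoldResult",
    "MissingEngineError",
    "energy_of",
    "fold_mfe",
    "enumerate_structures",
    "fold_external",
    "parse_pairs",
]

INF = 1e17
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the simplified nearest-neighbour loop model (kcal/mol)."""

    stack_gc: float = -3.0
    stack_au: float = -2.0
    stack_gu: float = -1.0
    hairpin_a: float = 3.0
    hairpin_b: float = 1.75
    internal_a: float = 2.0
    internal_b: float = 1.75
    ml_init: float = 3.4
    ml_branch: float = 0.4
    ml_unpaired: float = 0.0
    min_hairpin_loop: int = 3
    max_internal_unpaired: int = 30

    def __post_init__(self) -> None:
        if max(self.stack_gc, self.stack_au, self.stack_gu) > 0:
            raise ValidationError("stack energies must be <= 0")
        if min(self.hairpin_a, self.internal_a, self.ml_unpaired) < 0:
            raise ValidationError("loop penalties must be >= 0")

    def pair_strength(self, a: str, b: str) -> int:
        """0 = not pairable; 1 = GU/UG, 2 = AU/UA, 3 = CG/GC."""
        pair = a + b
        if pair in ("GC", "CG"):
            return 3
        if pair in ("AU", "UA"):
            return 2
        if pair in ("GU", "UG"):
            return 1
        return 0

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        """Energy of stacking two adjacent pairs: the weaker pair decides."""
        s = min(self.pair_strength(*outer), self.pair_strength(*inner))
        if s == 0:
            raise ValidationError(f"unstackable pairs {outer} / {inner}")
        return (self.stack_gu, self.stack_au, self.stack_gc)[s - 1]

    def hairpin(self, loop_len: int) -> float:
        if loop_len < self.min_hairpin_loop:
            raise ValidationError(
                f"hairpin loop of {loop_len} < minimum {self.min_hairpin_loop}"
            )
        return self.hairpin_a + self.hairpin_b * math.log(loop_len / 3.0)

    def internal(self, unpaired: int) -> float:
        if unpaired < 1:
            raise ValidationError("internal/bulge loop needs >= 1 unpaired nt")
        return self.internal_a + self.internal_b * math.log(unpaired)

    def multiloop(self, n_branches: int, unpaired: int) -> float:
        """n_branches counts every helix in the loop, closing one included."""
        return self.ml_init + self.ml_branch * n_branches + self.ml_unpaired * unpaired


@dataclass(frozen=True)
class FoldResult:
    structure: str
    energy: float
    provenance: str = "internal"


class MissingEngineError(RuntimeError):
    """The optional external folding engine is not installed."""


# ---------------------------------------------------------------------------
# structure parsing and scoring


def parse_pairs(structure: str) -> dict[int, int]:
    """Dot-bracket -> symmetric pair map; raises on unbalanced brackets."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValidationError(f"invalid structure character {ch!r} at {i}")
    if stack:
        raise ValidationError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def energy_of(
    gene: GeneRecord | str, structure: str, model: EnergyModel = EnergyModel()
) -> float:
    """Score a dot-bracket structure by its loop decomposition.

    The empty (all-dots) structure scores exactly 0; external unpaired
    bases are free.
    """
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene
    if len(seq) != len(structure):
        raise ValidationError(
            f"sequence length {len(seq)} != structure length {len(structure)}"
        )
    pairs = parse_pairs(structure)
    for i, j in pairs.items():
        if i < j and model.pair_strength(seq[i], seq[j]) == 0:
            raise ValidationError(f"disallowed pair {seq[i]}{seq[j]} at ({i},{j})")

    total = 0.0
    opening = sorted(i for i, j in pairs.items() if i < j)
    for i in opening:
        j = pairs[i]
        # find children pairs directly nested in (i, j)
        children: list[tuple[int, int]] = []
        unpaired = 0
        t = i + 1
        while t < j:
            if t in pairs:
                children.append((t, pairs[t]))
                t = pairs[t] + 1
            else:
                unpaired += 1
                t += 1
        if not children:
            total += model.hairpin(j - i - 1)
        elif len(children) == 1:
            p, q = children[0]
            if p == i + 1 and q == j - 1:
                total += model.stack_energy((seq[i], seq[j]), (seq[p], seq[q]))
            else:
                total += model.internal(unpaired)
        else:
            total += model.multiloop(1 + len(children), unpaired)
    return total


# ---------------------------------------------------------------------------
# Zuker-style dynamic program


@njit(cache=True, fastmath=True)
def _fill_matrices(enc, strength, stack_e, hp, ipen, max_u, ml_a, ml_b, ml_c, min_hp):
    """Zuker fill with candidate-list sparsification of the bifurcations.

    WM[i,j]: min energy of >= 1 multiloop branch inside [i, j] (branch
    penalty ml_b per helix, ml_c per unpaired nt). B[i,j]: same but >= 2
    branches, so a multiloop closed by (i-1, j+1) costs ml_a + ml_b + B.
    Because ml_c >= 0 makes WM subadditive under concatenation, only
    "candidate" helices (k, j) — those where V[k,j] + ml_b undercuts every
    decomposition of [k, j] — can appear as the last branch of an optimal
    split, which drops the bifurcation scans from O(L) to the candidate
    count per column.
    """
    L = enc.shape[0]
    V = np.full((L, L), INF)
    WM = np.full((L, L), INF)
    B = np.full((L, L), INF)
    cand_pos = np.zeros((L, L), dtype=np.int32)  # per column j, rows with
    cand_count = np.zeros(L, dtype=np.int64)  # candidate helices (k, j)
    span_min = min_hp + 1  # minimum j - i for a pair
    seg_min = min_hp + 2  # minimum nt a helix occupies

    for d in range(span_min, L):
        for i in range(0, L - d):
            j = i + d
            # --- V: (i, j) paired
            v = INF
            s1 = strength[enc[i], enc[j]]
            if s1 > 0:
                best = hp[d - 1]  # hairpin, loop length j - i - 1
                # stack on (i+1, j-1)
                if d - 2 >= span_min:
                    s2 = strength[enc[i + 1], enc[j - 1]]
                    if s2 > 0 and V[i + 1, j - 1] < INF / 2:
                        s = s1 if s1 < s2 else s2
                        cand = V[i + 1, j - 1] + stack_e[s]
                        if cand < best:
                            best = cand
                # internal / bulge to inner pair (p, q), 1..max_u unpaired;
                # V is INF at unpairable (p, q), so no pairability branch
                u_lim = max_u if max_u < d else d
                for u1 in range(0, u_lim + 1):
                    p = i + 1 + u1
                    u2_start = 1 if u1 == 0 else 0
                    for u2 in range(u2_start, u_lim - u1 + 1):
                        q = j - 1 - u2
                        if q - p < span_min:
                            break
                        cand = V[p, q] + ipen[u1 + u2]
                        if cand < best:
                            best = cand
                # multiloop closed by (i, j): >= 2 branches inside (i+1, j-1)
                if d - 2 >= 2 * seg_min and B[i + 1, j - 1] < INF / 2:
                    cand = ml_a + ml_b + B[i + 1, j - 1]
                    if cand < best:
                        best = cand
                v = best
                V[i, j] = v
            nc = cand_count[j]
            # --- B: >= 2 branches; last helix is a candidate (k, j), or
            # j is unpaired
            bb = B[i, j - 1] + ml_c
            for t in range(nc):
                k = cand_pos[j, t]
                if k >= i + seg_min:
                    cand = WM[i, k - 1] + V[k, j] + ml_b
                    if cand < bb:
                        bb = cand
            B[i, j] = bb
            # --- WM: >= 1 branch; i or j unpaired, or last helix (k, j)
            # with optional branches before it
            wm = WM[i + 1, j] + ml_c
            alt = WM[i, j - 1] + ml_c
            if alt < wm:
                wm = alt
            for t in range(nc):
                k = cand_pos[j, t]
                if k > i:
                    pre = ml_c * (k - i)  # all of [i, k-1] unpaired
                    if WM[i, k - 1] < pre:
                        pre = WM[i, k - 1]
                    cand = V[k, j] + ml_b + pre
                    if cand < wm:
                        wm = cand
            # helix (i, j) itself; record as candidate when it undercuts
            # every alternative decomposition of [i, j]
            if v < INF / 2:
                c_ij = v + ml_b
                if c_ij < wm:
                    cand_pos[j, nc] = i
                    cand_count[j] = nc + 1
                    wm = c_ij
            WM[i, j] = wm
    return V, WM, B, cand_pos, cand_count


@njit(cache=True, fastmath=True)
def _external_array(V, min_hp):
    L = V.shape[0]
    W = np.zeros(L)
    for j in range(L):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j - min_hp):
            if V[i, j] < INF / 2:
                left = W[i - 1] if i > 0 else 0.0
                cand = left + V[i, j]
                if cand < best:
                    best = cand
        W[j] = best
    return W


def _model_tables(model: EnergyModel, L: int):
    strength = np.zeros((4, 4), dtype=np.int8)
    for a, ia in _BASE_INDEX.items():
        for b, ib in _BASE_INDEX.items():
            strength[ia, ib] = EnergyModel.pair_strength(model, a, b)
    stack_e = np.array([0.0, model.stack_gu, model.stack_au, model.stack_gc])
    hp = np.full(max(L + 1, model.min_hairpin_loop + 1), INF)
    for l in range(model.min_hairpin_loop, L + 1):
        hp[l] = model.hairpin(l)
    max_u = model.max_internal_unpaired
    ipen = np.full(max_u + 1, INF)
    for u in range(1, max_u + 1):
        ipen[u] = model.internal(u)
    return strength, stack_e, hp, ipen


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"invalid RNA base {exc.args[0]!r}") from exc


_TOL = 1e-6


class _Traceback:
    """Reconstruct one optimal structure from the filled matrices.

    Case order within each cell prefers expansions that add no base pair,
    so among co-minimal local alternatives the sparser structure wins.
    """

    def __init__(self, enc, V, WM, B, cand_pos, cand_count, W, model, tables):
        self.enc, self.V, self.WM, self.B, self.W = enc, V, WM, B, W
        self.cand_pos, self.cand_count = cand_pos, cand_count
        self.model = model
        self.strength, self.stack_e, self.hp, self.ipen = tables
        self.struct = ["."] * len(enc)
        self.tasks: list[tuple[str, int, int]] = []

    def run(self) -> str:
        self._trace_W(len(self.enc) - 1)
        while self.tasks:
            kind, i, j = self.tasks.pop()
            if kind == "V":
                self._trace_V(i, j)
            elif kind == "B":
                self._trace_B(i, j)
            else:
                self._trace_WM(i, j)
        return "".join(self.struct)

    def _candidates(self, j: int):
        return self.cand_pos[j, : self.cand_count[j]]

    def _trace_W(self, j: int) -> None:
        model = self.model
        while j >= 0:
            prev = self.W[j - 1] if j > 0 else 0.0
            if abs(self.W[j] - prev) < _TOL:
                j -= 1
                continue
            n = j - model.min_hairpin_loop
            left = np.empty(n)
            left[0] = 0.0
            left[1:] = self.W[: n - 1]
            hits = np.nonzero(np.abs(left + self.V[:n, j] - self.W[j]) < _TOL)[0]
            if hits.size:
                i = int(hits[0])
                self.tasks.append(("V", i, j))
                j = i - 1
            else:  # numerically impossible; degrade to unpaired
                j -= 1

    def _trace_V(self, i: int, j: int) -> None:
        model, enc, V = self.model, self.enc, self.V
        span_min = model.min_hairpin_loop + 1
        seg_min = model.min_hairpin_loop + 2
        while True:  # iterative: stacks can be thousands deep
            self.struct[i], self.struct[j] = "(", ")"
            d = j - i
            e = V[i, j]
            if abs(e - self.hp[d - 1]) < _TOL:
                return
            if d - 2 >= span_min:
                s2 = self.strength[enc[i + 1], enc[j - 1]]
                s1 = self.strength[enc[i], enc[j]]
                if s2 > 0 and V[i + 1, j - 1] < INF / 2:
                    cand = V[i + 1, j - 1] + self.stack_e[min(s1, s2)]
                    if abs(cand - e) < _TOL:
                        i, j = i + 1, j - 1
                        continue
            found = False
            u_lim = min(model.max_internal_unpaired, d)
            for u1 in range(0, u_lim + 1):
                p = i + 1 + u1
                for u2 in range(1 if u1 == 0 else 0, u_lim - u1 + 1):
                    q = j - 1 - u2
                    if q - p < span_min:
                        break
                    if self.strength[enc[p], enc[q]] > 0 and V[p, q] < INF / 2:
                        if abs(V[p, q] + self.ipen[u1 + u2] - e) < _TOL:
                            i, j = p, q
                            found = True
                            break
                if found:
                    break
            if found:
                continue
            if (
                d - 2 >= 2 * seg_min
                and self.B[i + 1, j - 1] < INF / 2
                and abs(model.ml_init + model.ml_branch + self.B[i + 1, j - 1] - e)
                < _TOL
            ):
                self.tasks.append(("B", i + 1, j - 1))
                return
            raise AssertionError(f"traceback failed at V[{i},{j}]")

    def _trace_B(self, i: int, j: int) -> None:
        model = self.model
        seg_min = model.min_hairpin_loop + 2
        while (
            self.B[i, j - 1] < INF / 2
            and abs(self.B[i, j - 1] + model.ml_unpaired - self.B[i, j]) < _TOL
        ):
            j -= 1
        for k in self._candidates(j):
            k = int(k)
            if k >= i + seg_min and self.WM[i, k - 1] < INF / 2:
                cand = self.WM[i, k - 1] + self.V[k, j] + model.ml_branch
                if abs(cand - self.B[i, j]) < _TOL:
                    self.tasks.append(("WM", i, k - 1))
                    self.tasks.append(("V", k, j))
                    return
        raise AssertionError(f"traceback failed at B[{i},{j}]")

    def _trace_WM(self, i: int, j: int) -> None:
        model = self.model
        while True:
            if (
                self.WM[i + 1, j] < INF / 2
                and abs(self.WM[i + 1, j] + model.ml_unpaired - self.WM[i, j]) < _TOL
            ):
                i += 1
                continue
            if (
                self.WM[i, j - 1] < INF / 2
                and abs(self.WM[i, j - 1] + model.ml_unpaired - self.WM[i, j]) < _TOL
            ):
                j -= 1
                continue
            break
        wm = self.WM[i, j]
        for k in self._candidates(j):
            k = int(k)
            if k < i:
                continue
            c_kj = self.V[k, j] + model.ml_branch
            # prefer the branch-only reading (fewer pairs before k)
            if abs(c_kj + model.ml_unpaired * (k - i) - wm) < _TOL:
                self._trace_V(k, j)
                return
            if k - i >= model.min_hairpin_loop + 2 and self.WM[i, k - 1] < INF / 2:
                if abs(c_kj + self.WM[i, k - 1] - wm) < _TOL:
                    self.tasks.append(("WM", i, k - 1))
                    self._trace_V(k, j)
                    return
        raise AssertionError(f"traceback failed at WM[{i},{j}]")


def fold_mfe(
    gene: GeneRecord | str,
    model: EnergyModel = EnergyModel(),
    with_structure: bool = True,
) -> FoldResult:
    """Minimum-free-energy fold under the internal model.

    Returns a witnessing pseudoknot-free structure via traceback; the
    energy is always <= 0 because the open chain is admissible. Pass
    ``with_structure=False`` to skip the traceback (the structure comes
    back empty) when only the energy is needed, e.g. for |MFE|/L profiling
    of many long transcripts.
    """
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene
    if not seq:
        raise ValidationError("cannot fold an empty sequence")
    enc = _encode(seq)
    L = len(seq)
    if L < model.min_hairpin_loop + 2:
        return FoldResult("." * L, 0.0)
    tables = _model_tables(model, L)
    strength, stack_e, hp, ipen = tables
    V, WM, B, cand_pos, cand_count = _fill_matrices(
        enc,
        strength,
        stack_e,
        hp,
        ipen,
        model.max_internal_unpaired,
        model.ml_init,
        model.ml_branch,
        model.ml_unpaired,
        model.min_hairpin_loop,
    )
    W = _external_array(V, model.min_hairpin_loop)
    energy = float(min(W[L - 1], 0.0))
    if energy >= -_TOL:
        return FoldResult("." * L, 0.0)
    if not with_structure:
        return FoldResult("", energy)
    structure = _Traceback(
        enc, V, WM, B, cand_pos, cand_count, W, model, tables
    ).run()
    return FoldResult(structure, energy)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def _all_structures(seq: str, model: EnergyModel):
    """Yield every pseudoknot-free structure obeying pairing constraints."""
    min_hp = model.min_hairpin_loop

    def gen(i: int, j: int):
        # structures of seq[i:j]
        if j - i <= 0:
            yield ""
            return
        for rest in gen(i + 1, j):
            yield "." + rest
        for t in range(i + min_hp + 1, j):
            if model.pair_strength(seq[i], seq[t]) > 0:
                for inner in gen(i + 1, t):
                    for rest in gen(t + 1, j):
                        yield "(" + inner + ")" + rest

    yield from gen(0, len(seq))


def enumerate_structures(
    gene: GeneRecord | str,
    model: EnergyModel = EnergyModel(),
    length_limit: int = 25,
) -> tuple[int, float, str]:
    """Exhaustively score all structures of a short sequence.

    Returns ``(count, min_energy, argmin_structure)``. The argmin tie-break
    is: lowest energy, then fewest base pairs, then lexicographically
    smallest dot-bracket string. Guarded to ``length_limit`` nt.
    """
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene
    if len(seq) > length_limit:
        raise ValidationError(
            f"enumeration limited to {length_limit} nt (got {len(seq)})"
        )
    count = 0
    best: tuple[float, int, str] | None = None
    for struct in _all_structures(seq, model):
        count += 1
        e = energy_of(seq, struct, model)
        key = (e, struct.count("("), struct)
        if best is None or key < best:
            best = key
    assert best is not None
    return count, best[0], best[2]


# ---------------------------------------------------------------------------
# external engine adapter


def fold_external(gene: GeneRecord | str, engine: str = "RNAfold") -> FoldResult:
    """Fold with an installed Turner-parameter engine (ViennaRNA RNAfold).

    Produces literature-comparable kcal/mol values. Raises
    ``MissingEngineError`` when the engine binary is not discoverable.
    """
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene
    exe = shutil.which(engine)
    if exe is None:
        raise MissingEngineError(
            f"optional dependency missing: {engine!r} not found on PATH; "
            "install ViennaRNA or use the internal model (fold_mfe)"
        )
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    match = re.match(r"([.()]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)$", lines[-1])
    if match is None:
        raise RuntimeError(f"could not parse {engine} output: {lines[-1]!r}")
    return FoldResult(match.group(1), float(match.group(2)), provenance=engine)
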