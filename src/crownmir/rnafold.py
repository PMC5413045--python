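"""Hairpin-oriented RNA secondary-structure prediction with a free-energy score.

The model is a deliberately small nearest-neighbour-style scheme built for
miRNA precursor gating, not ensemble thermodynamics.  A structure is a set of
nested base pairs (Watson-Crick AU/GC plus GU wobble); its energy is the sum
of stacking terms over adjacent pairs, a fixed +4.0 kcal/mol closing penalty
per hairpin loop and +3.0 kcal/mol per bulge/internal loop.  Unpaired bases
outside any loop contribute nothing.  ``fold_mfe`` computes the exact minimum
over all nested structures by dynamic programming (Zuker-style V/W recursions
with O(1) internal-loop handling, possible because the internal-loop penalty
is length-independent).

The gate the pipeline cares about is the -20 kcal/mol precursor threshold;
simulated precursors are designed with >=5 kcal/mol margin below it so that
gate decisions are robust to the exact parameterisation.  The stacking table
can be overridden (e.g. swapped for a Turner-style table read from TSV) via
``EnergyModel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "fold_mfe",
    "score_energy",
    "pair_type",
]

#: valid base pairs -> pair class
_PAIR_CLASS = {
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("G", "U"): "GU", ("U", "G"): "GU",
}

MIN_HAIRPIN_LOOP = 3  # nt enclosed by an innermost pair


@dataclass(frozen=True)
class EnergyModel:
    """Energy parameters, kcal/mol.

    ``stack_homo`` holds the stacking term of two adjacent pairs of the same
    class; a mixed stack scores the mean of the two homogeneous values.
    """

    stack_homo: dict = field(default_factory=lambda: {"GC": -3.3, "AU": -0.9, "GU": -0.5})
    hairpin_penalty: float = 4.0
    internal_penalty: float = 3.0  # any bulge or internal loop
    multiloop_penalty: float = 0.0

    def stack(self, outer: str, inner: str) -> float:
        return 0.5 * (self.stack_homo[outer] + self.stack_homo[inner])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyModel":
        """Read a parameter table (rows: ``name<TAB>value``)."""
        stack = {}
        extras = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")
            if key.startswith("stack_"):
                stack[key.removeprefix("stack_")] = float(value)
            else:
                extras[key] = float(value)
        return cls(stack_homo=stack or cls().stack_homo, **extras)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"stack_{k}\t{v}" for k, v in sorted(self.stack_homo.items())]
        lines += [
            f"hairpin_penalty\t{self.hairpin_penalty}",
            f"internal_penalty\t{self.internal_penalty}",
            f"multiloop_penalty\t{self.multiloop_penalty}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_MODEL = EnergyModel()


def pair_type(a: str, b: str) -> str | None:
    """Pair class (``"AU"``/``"GC"``/``"GU"``) or None if not pairable."""
    return _PAIR_CLASS.get((a, b))


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its energy.

    ``pairs`` are 0-based ``(i, j)`` with ``i < j``.
    """

    sequence: str
    pairs: frozenset
    energy: float

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _to_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")
    return seq


def _validate_pairs(seq: str, pairs) -> list:
    """Check structure invariants; return pairs sorted by opening index."""
    n = len(seq)
    seen = set()
    plist = sorted(pairs)
    for i, j in plist:
        if not (0 <= i < j < n):
            raise ValueError(f"pair {(i, j)} out of bounds")
        if pair_type(seq[i], seq[j]) is None:
            raise ValueError(f"pair {(i, j)} = {seq[i]}:{seq[j]} is not AU/GC/GU")
        if i in seen or j in seen:
            raise ValueError(f"index in more than one pair near {(i, j)}")
        seen.update((i, j))
    # nestedness: no crossing pairs
    for a, (i, j) in enumerate(plist):
        for k, l in plist[a + 1:]:
            if k > j:
                break
            if i < k < j < l:
                raise ValueError(f"pseudoknot: {(i, j)} crosses {(k, l)}")
    return plist


def score_energy(structure: SecondaryStructure, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy (kcal/mol) of a structure under the loop-decomposition model.

    Raises ``ValueError`` if the structure violates the invariants (crossing
    pairs, non-canonical pairs, re-used indices, hairpin loop < 3 nt).
    """
    seq = _to_rna(structure.sequence)
    plist = _validate_pairs(seq, structure.pairs)

    # children: pairs directly enclosed by each pair
    children = {p: [] for p in plist}
    nesting = []
    for p in plist:  # sorted by opening index; maintain the enclosing chain
        while nesting and p[0] > nesting[-1][1]:
            nesting.pop()
        if nesting:
            children[nesting[-1]].append(p)
        nesting.append(p)

    energy = 0.0
    for (i, j), kids in children.items():
        if not kids:
            if j - i - 1 < MIN_HAIRPIN_LOOP:
                raise ValueError(
                    f"hairpin loop closed by {(i, j)} shorter than {MIN_HAIRPIN_LOOP} nt")
            energy += model.hairpin_penalty
        elif len(kids) == 1:
            (k, l) = kids[0]
            if (k, l) == (i + 1, j - 1):
                energy += model.stack(pair_type(seq[i], seq[j]), pair_type(seq[k], seq[l]))
            else:
                energy += model.internal_penalty
        else:
            energy += model.multiloop_penalty
    return energy


# ------------------------------------------------------------------
# minimum-free-energy folding
# ------------------------------------------------------------------
# All energy terms are exact multiples of 0.05 kcal/mol, so the DP runs on
# integers (unit 0.05 kcal/mol) with the pair count packed into the low bits
# for the fewer-pairs tie-break: state = energy_units * 512 + n_pairs.

_SCALE = 20  # integer units per kcal/mol
_PACK = 512  # > maximum possible number of pairs
_INF = 1 << 40


def fold_mfe(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Exact minimum-energy nested structure of ``sequence``.

    The empty structure (energy 0) is always admissible, so the returned
    energy is <= 0.  Sequence must be >= 10 nt over ACGU (T auto-converted).
    Ties are broken toward fewer pairs (exactly, via the DP state), then by a
    deterministic traceback that prefers earlier-opening pairs.
    """
    seq = _to_rna(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} < 10 nt)")

    def units(x: float) -> int:
        return round(x * _SCALE)

    hairpin_u = units(model.hairpin_penalty) * _PACK + 1
    internal_u = units(model.internal_penalty) * _PACK + 1
    multi_u = units(model.multiloop_penalty) * _PACK + 1
    stack_u = {}
    for a in model.stack_homo:
        for b in model.stack_homo:
            stack_u[(a, b)] = units(model.stack(a, b)) * _PACK + 1

    min_span = MIN_HAIRPIN_LOOP + 1
    ptype = [[None] * n for _ in range(n)]
    for i in range(n):
        row = ptype[i]
        for j in range(i + min_span, n):
            row[j] = _PAIR_CLASS.get((seq[i], seq[j]))

    V = [[_INF] * n for _ in range(n)]      # best with (i, j) paired
    Vmin = [[_INF] * n for _ in range(n)]   # min of V over all subintervals
    W = [[0] * n for _ in range(n)]         # >= 0 closed branches, empty = 0
    W1 = [[_INF] * n for _ in range(n)]     # >= 1 branch
    W2 = [[_INF] * n for _ in range(n)]     # >= 2 branches

    for span in range(min_span, n):
        for i in range(n - span):
            j = i + span
            pt = ptype[i][j]
            Vi = V[i]
            if pt is not None:
                best = hairpin_u
                if j - i >= min_span + 2:
                    inner = ptype[i + 1][j - 1]
                    vin = V[i + 1][j - 1]
                    if inner is not None and vin < _INF:
                        cand = vin + stack_u[(pt, inner)]
                        if cand < best:
                            best = cand
                    vm = Vmin[i + 1][j - 1]
                    if vm < _INF:
                        cand = vm + internal_u
                        if cand < best:
                            best = cand
                    w2 = W2[i + 1][j - 1]
                    if w2 < _INF:
                        cand = w2 + multi_u
                        if cand < best:
                            best = cand
                Vi[j] = best
            m = Vi[j]
            if Vmin[i + 1][j] < m:
                m = Vmin[i + 1][j]
            if Vmin[i][j - 1] < m:
                m = Vmin[i][j - 1]
            Vmin[i][j] = m
            # W-type recursions: skip i, or open a branch (i, l)
            w = W[i + 1][j]
            w1 = W1[i + 1][j]
            w2 = W2[i + 1][j]
            for l in range(i + min_span, j + 1):
                vil = Vi[l]
                if vil >= _INF:
                    continue
                rest = W[l + 1][j] if l + 1 <= j else 0
                cand = vil + rest
                if cand < w:
                    w = cand
                if cand < w1:
                    w1 = cand
                if l + 1 <= j:
                    rest1 = W1[l + 1][j]
                    if rest1 < _INF and vil + rest1 < w2:
                        w2 = vil + rest1
            if w > 0:
                w = 0  # the empty structure
            W[i][j] = w
            W1[i][j] = w1
            W2[i][j] = w2

    pairs: list = []

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i][j]
        if target == hairpin_u:
            return
        pt = ptype[i][j]
        inner = ptype[i + 1][j - 1]
        if inner is not None and V[i + 1][j - 1] < _INF and \
                V[i + 1][j - 1] + stack_u[(pt, inner)] == target:
            trace_V(i + 1, j - 1)
            return
        vm = Vmin[i + 1][j - 1]
        if vm < _INF and vm + internal_u == target:
            for k in range(i + 1, j):
                for l in range(k + min_span, j):
                    if V[k][l] == vm:
                        trace_V(k, l)
                        return
            raise AssertionError("traceback failed in V interior")  # pragma: no cover
        if W2[i + 1][j - 1] < _INF and W2[i + 1][j - 1] + multi_u == target:
            trace_Wk(i + 1, j - 1, 2)
            return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_W(i: int, j: int) -> None:
        while i <= j:
            target = W[i][j]
            opened = False
            for l in range(i + min_span, j + 1):
                if V[i][l] >= _INF:
                    continue
                rest = W[l + 1][j] if l + 1 <= j else 0
                if V[i][l] + rest == target:
                    trace_V(i, l)
                    i = l + 1
                    opened = True
                    break
            if opened:
                continue
            if i + 1 <= j and W[i + 1][j] == target:
                i += 1
                continue
            if target == 0:
                return
            raise AssertionError("traceback failed in W")  # pragma: no cover

    def trace_Wk(i: int, j: int, k: int) -> None:
        arr = W1 if k == 1 else W2
        while i <= j:
            target = arr[i][j]
            for l in range(i + min_span, j + 1):
                if V[i][l] >= _INF:
                    continue
                if k == 2:
                    rest = W1[l + 1][j] if l + 1 <= j else _INF
                    if rest < _INF and V[i][l] + rest == target:
                        trace_V(i, l)
                        trace_Wk(l + 1, j, 1)
                        return
                else:
                    rest = W[l + 1][j] if l + 1 <= j else 0
                    if V[i][l] + rest == target:
                        trace_V(i, l)
                        trace_W(l + 1, j)
                        return
            if i + 1 <= j and arr[i + 1][j] == target:
                i += 1
                continue
            raise AssertionError("traceback failed in W1/W2")  # pragma: no cover

    best = W[0][n - 1]
    if best >= 0:
        return SecondaryStructure(seq, frozenset(), 0.0)
    trace_W(0, n - 1)
    npairs = best % _PACK
    energy = ((best - npairs) // _PACK) / _SCALE
    assert npairs == len(pairs), "pair-count mismatch between DP state and traceback"
    return SecondaryStructure(seq, frozenset(pairs), energy)
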