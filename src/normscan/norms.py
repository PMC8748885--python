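"""Deterministic social norms over k public reputation labels.

A *norm* is the pair of an assignment rule ``R(X, Y, A) -> Z`` (the new
reputation a donor with reputation X earns after taking action A toward a
recipient with reputation Y) and an action rule ``P(X, Y) -> A`` (the action
prescribed to that donor).  Reputations are mere labels with no a-priori
order, so norms related by a relabelling of the reputation alphabet are
equivalent; this module provides the fixed serialisation, the integer
encoding, the permutation action, canonical orbit representatives, and the
standard constructible families (the leading eight for the binary model,
second-order norms for the ternary one).

Alphabet conventions (fixed per ``k`` and used for every serialisation):

* ``k = 3``: ``B < N < G`` (bad, neutral, good), indices 0, 1, 2.
* ``k = 2``: ``B < G``, indices 0, 1.

Actions are ``C`` (cooperate, index 0) and ``D`` (defect, index 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABETS",
    "ACTIONS",
    "Norm",
    "parse_norm",
    "parse_norm_text",
    "permute_norm",
    "canonicalize",
    "all_permutations",
    "count_assignment_orbits",
    "count_action_orbits",
    "count_joint_orbits",
    "leading_eight",
    "second_order_norms",
    "second_order_norm",
    "embed_binary",
    "merge_labels",
]

#: Reputation alphabets, ordered worst-to-best by convention.
ALPHABETS = {2: "BG", 3: "BNG"}

#: Action alphabet; C sorts before D in all encodings.
ACTIONS = "CD"

C, D = 0, 1


def _alphabet(k: int) -> str:
    try:
        return ALPHABETS[k]
    except KeyError:
        if k > 3:
            # The formulas generalise; give larger k a deterministic alphabet.
            return "".join(chr(ord("a") + i) for i in range(k))
        raise ValueError(f"k must be >= 2, got {k}") from None


@dataclass(frozen=True)
class Norm:
    """A deterministic social norm: assignment rule R and action rule P.

    Attributes
    ----------
    k
        Number of reputation labels.
    assignment
        Integer array of shape ``(k, k, 2)``; ``assignment[x, y, a]`` is the
        index of the donor's new reputation Z = R(X, Y, A).
    action
        Integer array of shape ``(k, k)`` with entries 0 (C) or 1 (D);
        ``action[x, y]`` is P(X, Y).
    """

    k: int
    assignment: np.ndarray = field(compare=False)
    action: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.assignment, dtype=np.int64)
        P = np.asarray(self.action, dtype=np.int64)
        if R.shape != (self.k, self.k, 2):
            raise ValueError(f"assignment table must be {self.k}x{self.k}x2")
        if P.shape != (self.k, self.k):
            raise ValueError(f"action table must be {self.k}x{self.k}")
        if R.min() < 0 or R.max() >= self.k:
            raise ValueError("assignment entries must be reputation indices")
        if P.min() < 0 or P.max() > 1:
            raise ValueError("action entries must be 0 (C) or 1 (D)")
        R.flags.writeable = False
        P.flags.writeable = False
        object.__setattr__(self, "assignment", R)
        object.__setattr__(self, "action", P)

    # -- derived tables -------------------------------------------------

    def on_path_assignment(self) -> np.ndarray:
        """R(X, Y) = R(X, Y, P(X, Y)): assignment along the prescribed action."""
        x, y = np.indices((self.k, self.k))
        return self.assignment[x, y, self.action]

    # -- integer encoding ----------------------------------------------

    @property
    def assignment_int(self) -> int:
        """Base-k integer over the 2k^2 digits R(X,Y,A), donor-major,
        then recipient, then action, most significant first."""
        digits = self.assignment.ravel()
        out = 0
        for d in digits:
            out = out * self.k + int(d)
        return out

    @property
    def action_int(self) -> int:
        """Base-2 integer over the k^2 bits P(X,Y), donor-major, MSB first."""
        out = 0
        for b in self.action.ravel():
            out = out * 2 + int(b)
        return out

    def encode(self) -> tuple[int, int]:
        return (self.assignment_int, self.action_int)

    @property
    def compact_id(self) -> str:
        """Decimal pair ``<assignment_int>-<action_int>``."""
        return f"{self.assignment_int}-{self.action_int}"

    @classmethod
    def from_ints(cls, k: int, assignment_int: int, action_int: int) -> "Norm":
        n_cells = 2 * k * k
        if not 0 <= assignment_int < k**n_cells:
            raise ValueError("assignment integer out of range")
        if not 0 <= action_int < 2 ** (k * k):
            raise ValueError("action integer out of range")
        digits = np.empty(n_cells, dtype=np.int64)
        v = assignment_int
        for i in range(n_cells - 1, -1, -1):
            digits[i] = v % k
            v //= k
        bits = np.empty(k * k, dtype=np.int64)
        v = action_int
        for i in range(k * k - 1, -1, -1):
            bits[i] = v % 2
            v //= 2
        return cls(k, digits.reshape(k, k, 2), bits.reshape(k, k))

    @classmethod
    def from_compact_id(cls, k: int, compact: str) -> "Norm":
        a, _, p = compact.partition("-")
        return cls.from_ints(k, int(a), int(p))

    # -- equality / hashing on the encoding -----------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Norm):
            return NotImplemented
        return self.k == other.k and self.encode() == other.encode()

    def __hash__(self) -> int:
        return hash((self.k, self.encode()))

    # -- serialisation ---------------------------------------------------

    def prescriptions(self) -> list[str]:
        """One ``XY:AZ:W`` quintuple per (donor, recipient) pair, donor-major."""
        alpha = _alphabet(self.k)
        rows = []
        for x in range(self.k):
            for y in range(self.k):
                a = int(self.action[x, y])
                z = int(self.assignment[x, y, a])
                w = int(self.assignment[x, y, 1 - a])
                rows.append(f"{alpha[x]}{alpha[y]}:{ACTIONS[a]}{alpha[z]}:{alpha[w]}")
        return rows

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Norm(k={self.k}, id={self.compact_id})"

    def __str__(self) -> str:
        return " ".join(self.prescriptions())


def parse_norm(rows: list[str], k: int | None = None) -> Norm:
    """Parse a norm from its prescription strings ``XY:AZ:W``.

    Exactly one row per (donor, recipient) pair is required, in any order.
    ``X``/``Y`` are reputation characters, ``A`` the prescribed action, ``Z``
    the reputation earned by following the prescription and ``W`` the one
    earned by the opposite action.

    Raises
    ------
    ValueError
        On duplicate or missing pairs, illegal characters, or a row set
        inconsistent with ``k``.
    """
    cleaned = []
    for raw in rows:
        row = raw.split("#", 1)[0].strip()
        if row:
            cleaned.append(row)
    if not cleaned:
        raise ValueError("no prescriptions given")
    if k is None:
        n = len(cleaned)
        k = math.isqrt(n)
        if k * k != n or k < 2:
            raise ValueError(f"cannot infer k from {n} prescriptions")
    alpha = _alphabet(k)
    rep = {ch: i for i, ch in enumerate(alpha)}
    act = {"C": C, "D": D}
    R = np.zeros((k, k, 2), dtype=np.int64)
    P = np.zeros((k, k), dtype=np.int64)
    seen: set[tuple[int, int]] = set()
    for row in cleaned:
        parts = row.split(":")
        if len(parts) != 3 or len(parts[0]) != 2 or len(parts[1]) != 2 or len(parts[2]) != 1:
            raise ValueError(f"malformed prescription {row!r} (expected 'XY:AZ:W')")
        try:
            x, y = rep[parts[0][0]], rep[parts[0][1]]
            a = act[parts[1][0]]
            z = rep[parts[1][1]]
            w = rep[parts[2]]
        except KeyError as exc:
            raise ValueError(f"illegal character {exc.args[0]!r} in {row!r} for k={k}") from None
        if (x, y) in seen:
            raise ValueError(f"duplicate prescription for pair {parts[0]!r}")
        seen.add((x, y))
        P[x, y] = a
        R[x, y, a] = z
        R[x, y, 1 - a] = w
    if len(seen) != k * k:
        missing = [
            alpha[x] + alpha[y]
            for x in range(k)
            for y in range(k)
            if (x, y) not in seen
        ]
        raise ValueError(f"missing prescriptions for pairs {missing}")
    return Norm(k, R, P)


def parse_norm_text(text: str, k: int | None = None) -> Norm:
    """Parse a prescription file: one quintuple per line, '#' comments allowed."""
    return parse_norm(text.splitlines(), k=k)


# ---------------------------------------------------------------------------
# Permutation action and canonical representatives
# ---------------------------------------------------------------------------


def all_permutations(k: int) -> list[tuple[int, ...]]:
    """The k! relabellings of the reputation alphabet."""
    return list(itertools.permutations(range(k)))


def permute_norm(norm: Norm, sigma: tuple[int, ...] | list[int]) -> Norm:
    """Relabel every reputation symbol by ``sigma`` (actions unchanged).

    ``sigma[i]`` is the new index of the reputation currently indexed ``i``,
    so the permuted tables satisfy ``R'(sx, sy, a) = s(R(x, y, a))`` and
    ``P'(sx, sy) = P(x, y)``.
    """
    sigma = tuple(sigma)
    if sorted(sigma) != list(range(norm.k)):
        raise ValueError(f"not a permutation of 0..{norm.k - 1}: {sigma}")
    s = np.asarray(sigma)
    inv = np.argsort(s)
    R = s[norm.assignment[np.ix_(inv, inv)]]
    P = norm.action[np.ix_(inv, inv)]
    return Norm(norm.k, R, P)


def canonicalize(norm: Norm) -> tuple[Norm, tuple[int, ...]]:
    """Orbit representative with the lexicographically smallest joint
    (assignment, action) encoding, plus one permutation achieving it.

    Idempotent and constant on permutation orbits.
    """
    best = None
    best_sigma = None
    for sigma in all_permutations(norm.k):
        cand = permute_norm(norm, sigma)
        key = cand.encode()
        if best is None or key < best.encode():
            best, best_sigma = cand, sigma
    return best, best_sigma


def _cycle_lengths(sigma: tuple[int, ...]) -> list[int]:
    seen = [False] * len(sigma)
    out = []
    for i in range(len(sigma)):
        if seen[i]:
            continue
        n, j = 0, i
        while not seen[j]:
            seen[j] = True
            j = sigma[j]
            n += 1
        out.append(n)
    return out


def _fixed_assignment_tables(k: int, sigma: tuple[int, ...]) -> int:
    """Number of assignment tables R with R(sx, sy, a) = s(R(x, y, a)).

    The permutation acts on the 2k^2 cells by (x, y, a) -> (sx, sy, a) and on
    the values by s; a table is fixed iff, on each cell cycle of length L, the
    value at a representative cell is fixed by sigma^L.
    """
    cells = [(x, y, a) for x in range(k) for y in range(k) for a in range(2)]
    index = {c: i for i, c in enumerate(cells)}
    perm_on_cells = [index[(sigma[x], sigma[y], a)] for (x, y, a) in cells]
    count = 1
    for L in _cycle_lengths(tuple(perm_on_cells)):
        # fixed points of sigma^L on the k values
        power = list(range(k))
        for _ in range(L):
            power = [sigma[i] for i in power]
        count *= sum(1 for i, j in enumerate(power) if i == j)
    return count


def _fixed_action_tables(k: int, sigma: tuple[int, ...]) -> int:
    """Number of action tables P with P(sx, sy) = P(x, y)."""
    pairs = [(x, y) for x in range(k) for y in range(k)]
    index = {p: i for i, p in enumerate(pairs)}
    perm = tuple(index[(sigma[x], sigma[y])] for (x, y) in pairs)
    return 2 ** len(_cycle_lengths(perm))


def count_assignment_orbits(k: int) -> int:
    """Permutation-equivalence classes of assignment rules (Burnside).

    The average, over the k! relabellings, of the number of assignment tables
    each relabelling fixes.  For ``k = 3`` this is 64,573,605, reducing the
    raw 3^18 = 387,420,489 tables.
    """
    perms = all_permutations(k)
    return sum(_fixed_assignment_tables(k, s) for s in perms) // len(perms)


def count_action_orbits(k: int) -> int:
    """Permutation-equivalence classes of action rules (Burnside)."""
    perms = all_permutations(k)
    return sum(_fixed_action_tables(k, s) for s in perms) // len(perms)


def count_joint_orbits(k: int) -> int:
    """Permutation-equivalence classes of full norms (assignment, action).

    Note the product ``count_assignment_orbits(k) * 2**(k*k)`` (assignment-only
    reduction with every action rule attached) over-counts joint orbits
    whenever a permutation fixes an assignment rule but not the attached
    action rule; both accountings are exposed.
    """
    perms = all_permutations(k)
    total = sum(
        _fixed_assignment_tables(k, s) * _fixed_action_tables(k, s) for s in perms
    )
    return total // len(perms)


# ---------------------------------------------------------------------------
# Constructible families
# ---------------------------------------------------------------------------


def leading_eight() -> list[Norm]:
    """The eight binary-reputation norms that sustain stable cooperation.

    All share maintenance of cooperation (GG:CG:B), justified punishment
    (GB:DG), identification of defectors (R(*,G,D) = B) and apology/
    forgiveness (BG:CG:B); the three remaining table entries R(G,B,C),
    R(B,B,C), R(B,B,D) are free, with P(B,B) = C exactly when
    R(B,B,C) = G and R(B,B,D) = B.  Wildcards are expanded in alphabet
    order (B before G), giving a deterministic list of 8 distinct norms.
    """
    b, g = 0, 1
    norms = []
    for r_gbc in (b, g):
        for r_bbc in (b, g):
            for r_bbd in (b, g):
                R = np.zeros((2, 2, 2), dtype=np.int64)
                P = np.zeros((2, 2), dtype=np.int64)
                # maintenance of cooperation
                P[g, g] = C
                R[g, g, C] = g
                R[g, g, D] = b
                # punishment and its justification
                P[g, b] = D
                R[g, b, D] = g
                R[g, b, C] = r_gbc
                # apology and forgiveness
                P[b, g] = C
                R[b, g, C] = g
                R[b, g, D] = b
                # B meets B: cooperate only if it pays and defection is punished
                R[b, b, C] = r_bbc
                R[b, b, D] = r_bbd
                P[b, b] = C if (r_bbc == g and r_bbd == b) else D
                norms.append(Norm(2, R, P))
    return norms


def second_order_norm(k: int, r: np.ndarray, p: np.ndarray) -> Norm:
    """Build the donor-independent norm with R(X, Y, A) = r[Y, A], P(X, Y) = p[Y]."""
    r = np.asarray(r, dtype=np.int64)
    p = np.asarray(p, dtype=np.int64)
    R = np.broadcast_to(r, (k, k, 2)).copy()
    P = np.broadcast_to(p, (k, k)).copy()
    return Norm(k, R, P)


def second_order_norms(k: int):
    """Yield every norm whose rules ignore the donor's reputation.

    There are ``k**(2k) * 2**k`` of them (5832 for k = 3), yielded in
    increasing order of their (assignment, action) encoding.
    """
    n_cells = 2 * k
    for digits in itertools.product(range(k), repeat=n_cells):
        r = np.asarray(digits, dtype=np.int64).reshape(k, 2)
        for bits in itertools.product(range(2), repeat=k):
            yield second_order_norm(k, r, np.asarray(bits, dtype=np.int64))


# ---------------------------------------------------------------------------
# Cross-k constructions
# ---------------------------------------------------------------------------


def embed_binary(norm: Norm) -> Norm:
    """Embed a binary (B, G) norm into the ternary alphabet with N unused.

    N-rows and N-columns copy the B behaviour and N is never assigned, so N
    arises only through assignment error and drains at the B rate; the
    embedded norm reproduces the binary dynamics up to O(mu) corrections.
    """
    if norm.k != 2:
        raise ValueError("embed_binary expects a k=2 norm")
    to3 = np.array([0, 2])  # B->B, G->G in the BNG alphabet
    proj = np.array([0, 0, 1])  # B,N -> binary B; G -> binary G
    R = np.zeros((3, 3, 2), dtype=np.int64)
    P = np.zeros((3, 3), dtype=np.int64)
    for x in range(3):
        for y in range(3):
            bx, by = proj[x], proj[y]
            P[x, y] = norm.action[bx, by]
            for a in range(2):
                R[x, y, a] = to3[norm.assignment[bx, by, a]]
    return Norm(3, R, P)


def merge_labels(norm: Norm, merged: tuple[int, int]) -> Norm | None:
    """Merge two reputation labels into one, if the rules allow it.

    Returns the induced binary norm (alphabet B', G' with the merged pair
    mapping to one label and the remaining label to the other, order
    preserved), or ``None`` when the merge is inconsistent, i.e. two cells
    identified by the merge prescribe different merged images or actions.
    """
    if norm.k != 3:
        raise ValueError("merge_labels expects a k=3 norm")
    a, b = sorted(merged)
    other = ({0, 1, 2} - {a, b}).pop()
    # keep alphabet order: merged class takes the slot of its smaller member
    order = sorted([a, other])
    phi = np.empty(3, dtype=np.int64)
    phi[a] = phi[b] = order.index(a)
    phi[other] = order.index(other)
    R = -np.ones((2, 2, 2), dtype=np.int64)
    P = -np.ones((2, 2), dtype=np.int64)
    for x in range(3):
        for y in range(3):
            px, py = phi[x], phi[y]
            act = int(norm.action[x, y])
            if P[px, py] == -1:
                P[px, py] = act
            elif P[px, py] != act:
                return None
            for ac in range(2):
                z = phi[norm.assignment[x, y, ac]]
                if R[px, py, ac] == -1:
                    R[px, py, ac] = z
                elif R[px, py, ac] != z:
                    return None
    return Norm(2, R, P)
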