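"""Classification of successful norms: relabelling convention, C/P/R taxonomy,
and stationary transition graphs.

Reputation labels carry no intrinsic meaning, so every norm is first brought
to the conventional labelling: the majority reputation at stationarity is
called G, the reputation earned by defecting in a G-G encounter is called B,
and the remaining one N.  Conventionally labelled cooperative ESSs then fall
into twelve subclasses:

* C1 / C2 / C3 by the scaling of the stationary neutral fraction ``h_N*``
  with the error rate mu (orders mu, sqrt(mu) and 1, measured as the log-log
  slope over a mu grid with band edges 0.25 and 0.75, the midpoints between
  the theoretical exponents);
* P1 / P2 by whether punishment of ill-reputed players is fully or only
  partially justified;
* R1 / R2 by whether a B-player recovers good standing in one step or
  gradually.

The punishment/recovery patterns are matched on the prescribed action and
the on-path assignment; the class definitions differ between C1/C2 and C3
because in C3 communities both G and N are "good" majority labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import (
    DEFAULT_MU_GRID,
    ErrorModel,
    StationaryResult,
    scaling_exponent,
    stationary,
)
from .norms import Norm, permute_norm

__all__ = [
    "NormClass",
    "UnclassifiableNorm",
    "NotRelabelable",
    "relabel_by_convention",
    "classify_c",
    "classify_p",
    "classify_r",
    "classify",
    "transition_graph",
    "graph_to_dot",
    "graph_to_json",
    "is_standing_or_judging",
    "merge_annotation",
]

B, N, G = 0, 1, 2
C, D = 0, 1


class UnclassifiableNorm(ValueError):
    """The norm matches none of the class-specific patterns; carries evidence."""


class NotRelabelable(ValueError):
    """No labelling satisfies the convention (majority G, B = R(G,G,D))."""


@dataclass(frozen=True)
class NormClass:
    """Subclass label of a conventionally relabelled cooperative ESS."""

    c_type: str
    p_type: str
    r_type: str
    scaling_slope: float
    evidence: dict = field(default_factory=dict, compare=False)

    @property
    def label(self) -> str:
        return f"{self.c_type}-{self.p_type}-{self.r_type}"


# ---------------------------------------------------------------------------
# Relabelling convention
# ---------------------------------------------------------------------------


def relabel_by_convention(
    norm: Norm,
    stat: StationaryResult | None = None,
    err: ErrorModel | None = None,
    tie_tol: float = 1e-6,
) -> tuple[Norm, tuple[int, ...]]:
    """Bring a norm to the conventional labelling.

    G is the reputation with the largest stationary share, B the reputation
    assigned after a defection between two G-players, and N the remaining
    one.  Near-ties in the shares (within ``tie_tol``) admit several G
    candidates; they are ranked by (strictly larger share, then smaller
    canonical encoding of the relabelled norm), which makes the choice
    deterministic at finite solver precision.

    Raises
    ------
    NotRelabelable
        If every admissible G candidate violates the convention, i.e.
        P(G, G) != C or R(G, G, D) lands back on the majority label (a
        defector keeping top standing cannot sustain a cooperative ESS).
    """
    if stat is None:
        stat = stationary(norm, err or ErrorModel())
    h = np.asarray(stat.h_star, dtype=float)
    k = norm.k
    top = h.max()
    candidates = [g for g in range(k) if h[g] >= top - tie_tol]
    options = []
    for g in candidates:
        if norm.action[g, g] != C:
            continue
        z = int(norm.assignment[g, g, D])
        if z == g:
            continue
        sigma = [0] * k
        if k == 2:
            sigma[g], sigma[z] = 1, 0
        else:
            rest = ({0, 1, 2} - {g, z}).pop()
            sigma[g], sigma[z], sigma[rest] = G, B, N
        relabeled = permute_norm(norm, tuple(sigma))
        options.append((-h[g], relabeled.encode(), relabeled, tuple(sigma)))
    if not options:
        raise NotRelabelable(
            "no labelling has a cooperating majority whose in-group defection "
            "is marked by a distinct (bad) label"
        )
    options.sort(key=lambda t: (t[0], t[1]))
    _, _, relabeled, sigma = options[0]
    return relabeled, sigma


# ---------------------------------------------------------------------------
# C / P / R classification
# ---------------------------------------------------------------------------

SLOPE_BANDS = (0.25, 0.75)  # midpoints between the exponents 0, 1/2, 1
SLOPE_RANGE = (-0.1, 1.25)


def classify_c(
    norm: Norm,
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID,
) -> tuple[str, float]:
    """C-type from the log-log slope of ``h_N*`` against mu.

    Slope > 0.75 -> C1 (h_N* = O(mu)); 0.25..0.75 -> C2 (O(sqrt mu));
    < 0.25 -> C3 (O(1)).  Slopes outside [-0.1, 1.25] are flagged.
    """
    slope, _, diag = scaling_exponent(norm, "h_N_star", mu_grid)
    if not (SLOPE_RANGE[0] <= slope <= SLOPE_RANGE[1]):
        raise UnclassifiableNorm(f"scaling slope {slope:.3f} outside {SLOPE_RANGE}", diag)
    lo, hi = SLOPE_BANDS
    c_type = "C1" if slope > hi else ("C2" if slope >= lo else "C3")
    return c_type, float(slope)


def classify_p(norm: Norm, c_type: str) -> str:
    """Punishment pattern of a conventionally relabelled norm.

    C1/C2: punishment of B by G must be prescribed (P(G,B) = D); P1 when the
    punisher keeps G (GB:DG), P2 when the punisher drops to N (GB:DN).
    C3: both G- and N-players must punish B; P1 when both punishments leave
    the punisher in good standing (image in {G, N}), P2 when exactly one of
    them sends the punisher to B.
    """
    R, P = norm.assignment, norm.action
    if c_type in ("C1", "C2"):
        if P[G, B] != D:
            raise UnclassifiableNorm(
                f"{c_type} punishment pattern needs P(G,B)=D, got C"
            )
        z = int(R[G, B, D])
        if z == G:
            return "P1"
        if z == N:
            return "P2"
        raise UnclassifiableNorm("punisher of B drops to B (GB:DB): unjustifiable")
    if c_type == "C3":
        if P[G, B] != D or P[N, B] != D:
            raise UnclassifiableNorm("C3 punishment pattern needs P(G,B)=P(N,B)=D")
        zg, zn = int(R[G, B, D]), int(R[N, B, D])
        good_g, good_n = zg in (G, N), zn in (G, N)
        if good_g and good_n:
            return "P1"
        if good_g != good_n:
            return "P2"
        raise UnclassifiableNorm("both punishments land on B: unjustifiable")
    raise ValueError(f"unknown c_type {c_type!r}")


def classify_r(norm: Norm, c_type: str) -> str:
    """Recovery pattern of a conventionally relabelled norm.

    C1: R1 when a B-player regains G at once by cooperating with G (BG:CG);
    R2 when the on-path route is two-step, B -> N (BG:.N) then N -> G
    (NG:.G), with either action allowed along the way.
    C2: R1 = BG:CG, R2 = BG:CN.
    C3: R1 when cooperating with either G or N lifts B into {G, N}; R2 when
    only one of the two encounters offers escape and the other is an on-path
    self-loop at B (BG:DB or BN:DB).
    """
    R, P = norm.assignment, norm.action
    on = norm.on_path_assignment()
    if c_type == "C1":
        if P[B, G] == C and R[B, G, C] == G:
            return "R1"
        if on[B, G] == N and on[N, G] == G:
            return "R2"
        raise UnclassifiableNorm("no C1 recovery route from B via G")
    if c_type == "C2":
        if P[B, G] == C and R[B, G, C] == G:
            return "R1"
        if P[B, G] == C and R[B, G, C] == N:
            return "R2"
        raise UnclassifiableNorm("no C2 recovery route (B must cooperate with G)")
    if c_type == "C3":
        esc_g = P[B, G] == C and R[B, G, C] in (G, N)
        esc_n = P[B, N] == C and R[B, N, C] in (G, N)
        loop_g = P[B, G] == D and R[B, G, D] == B
        loop_n = P[B, N] == D and R[B, N, D] == B
        if esc_g and esc_n:
            return "R1"
        if (esc_g and loop_n) or (esc_n and loop_g):
            return "R2"
        raise UnclassifiableNorm("no C3 recovery route from B")
    raise ValueError(f"unknown c_type {c_type!r}")


def classify(
    norm: Norm,
    err: ErrorModel | None = None,
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID,
    stat: StationaryResult | None = None,
    relabeled: bool = False,
) -> NormClass:
    """Full subclass label of a norm (relabel, then C, P and R patterns)."""
    err = err or ErrorModel()
    if not relabeled:
        norm, sigma = relabel_by_convention(norm, stat=stat, err=err)
    else:
        sigma = tuple(range(norm.k))
    c_type, slope = classify_c(norm, mu_grid)
    p_type = classify_p(norm, c_type)
    r_type = classify_r(norm, c_type)
    return NormClass(
        c_type=c_type,
        p_type=p_type,
        r_type=r_type,
        scaling_slope=slope,
        evidence={"sigma": sigma, "prescriptions": norm.prescriptions()},
    )


# ---------------------------------------------------------------------------
# Stationary transition graphs
# ---------------------------------------------------------------------------


def transition_graph(
    norm: Norm,
    stat: StationaryResult,
    err: ErrorModel,
    threshold: float | None = None,
    include_misassignment: bool | None = None,
) -> nx.MultiDiGraph:
    """Weighted reputation-transition graph at stationarity.

    An edge ``XY:AZ`` moves a donor from X to Z by taking action A toward a
    recipient with reputation Y; its weight is the stationary probability
    flow ``h*_X h*_Y P(action = A)``.  Edges driven by implementation error
    (A different from the prescription) carry ``error=True`` and render
    dashed.  By default only prescription-resolved transitions
    (Z = R(X, Y, A)) at weight >= mu^1.5 are kept — the geometric separator
    between the O(mu) flows that carry the mechanism and the O(mu^2) noise
    floor; ``threshold=0`` keeps everything and then also emits the pure
    misassignment edges (Z != R(X, Y, A), ``misassigned=True``) unless
    explicitly disabled.
    """
    k = norm.k
    alpha = {2: "BG", 3: "BNG"}[k]
    mu = max(err.mu_e, err.mu_a, 1e-12)
    if threshold is None:
        threshold = mu**1.5
    if include_misassignment is None:
        include_misassignment = threshold == 0
    h = np.asarray(stat.h_star, dtype=float)
    wrong = err.mu_a / (k - 1)
    keep = 1.0 - err.mu_a  # probability the prescribed label is retained

    G_ = nx.MultiDiGraph()
    for x in range(k):
        G_.add_node(alpha[x], h_star=round(float(h[x]), 4))
    for x in range(k):
        for y in range(k):
            prescribed = int(norm.action[x, y])
            p_act = {C: 0.0, D: 1.0}
            if prescribed == C:
                p_act = {C: 1.0 - err.mu_e, D: err.mu_e}
            for a, pa in p_act.items():
                if pa == 0.0 and threshold > 0:
                    continue  # threshold 0 keeps even never-taken actions
                z_on = int(norm.assignment[x, y, a])
                base = float(h[x] * h[y] * pa)
                if include_misassignment:
                    targets = [(z_on, base * keep, False)] + [
                        (z, base * wrong, True) for z in range(k) if z != z_on
                    ]
                else:
                    # aggregate the (1 - mu_a k/(k-1)) retention into the
                    # displayed action flow; misassignment is O(mu) noise
                    targets = [(z_on, base, False)]
                for z, w, mis in targets:
                    if w < threshold:
                        continue
                    G_.add_edge(
                        alpha[x],
                        alpha[z],
                        context=f"{alpha[x]}{alpha[y]}",
                        action="CD"[a],
                        label=f"{alpha[x]}{alpha[y]}:{'CD'[a]}{alpha[z]}",
                        weight=w,
                        error=a != prescribed,
                        misassigned=mis,
                    )
    return G_


def graph_to_dot(graph: nx.MultiDiGraph) -> str:
    """DOT serialisation: dashed edges mark implementation-error moves."""
    lines = ["digraph reputation {"]
    for node, data in graph.nodes(data=True):
        lines.append(f'  {node} [label="{node}\\n{data.get("h_star", 0):.4f}"];')
    for u, v, data in graph.edges(data=True):
        style = "dashed" if data.get("error") else "solid"
        if data.get("misassigned"):
            style = "dotted"
        lines.append(
            f'  {u} -> {v} [label="{data["label"]}", style={style}, '
            f'penwidth={max(0.3, 6 * data["weight"]):.2f}, weight_value={data["weight"]:.3e}];'
        )
    lines.append("}")
    return "\n".join(lines)


def graph_to_json(graph: nx.MultiDiGraph) -> str:
    """JSON edge-list serialisation with node shares and edge attributes."""
    payload = {
        "nodes": [
            {"id": n, "h_star": data.get("h_star")} for n, data in graph.nodes(data=True)
        ],
        "edges": [
            {
                "from": u,
                "to": v,
                "label": data["label"],
                "weight": data["weight"],
                "error": bool(data["error"]),
                "misassigned": bool(data.get("misassigned", False)),
            }
            for u, v, data in graph.edges(data=True)
        ],
    }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Relation to the binary second-order norms
# ---------------------------------------------------------------------------


def is_standing_or_judging(norm: Norm) -> bool:
    """Whether a binary norm belongs to the Simple Standing / Stern Judging
    family: donor-independent with P(.,G)=C, P(.,B)=D, R(.,G,C)=G,
    R(.,G,D)=B and R(.,B,D)=G (the image of cooperating with B is free)."""
    if norm.k != 2:
        raise ValueError("expects a binary norm")
    b, g = 0, 1
    R, P = norm.assignment, norm.action
    for x in range(2):
        if P[x, g] != C or P[x, b] != D:
            return False
        if R[x, g, C] != g or R[x, g, D] != b or R[x, b, D] != g:
            return False
    # donor independence of the free entry as well
    return R[0, b, C] == R[1, b, C]


def _matches_merged_ss_sj(norm: Norm, good: set[int]) -> bool:
    """Does the norm reduce to the SS/SJ family when the labels in ``good``
    merge into the single good reputation and the rest into the bad one?

    The family constrains every cell except the image of cooperating with a
    bad recipient (the SS-vs-SJ wildcard), so merges that disagree only
    there still count as equivalent.
    """
    bad = set(range(norm.k)) - good
    R, P = norm.assignment, norm.action
    for x in range(norm.k):
        for y in range(norm.k):
            if y in good:
                if P[x, y] != C:
                    return False
                if int(R[x, y, C]) not in good or int(R[x, y, D]) not in bad:
                    return False
            else:
                if P[x, y] != D:
                    return False
                if int(R[x, y, D]) not in good:
                    return False
                # R[x, y, C] is the family's free cell
    return True


def merge_annotation(norm: Norm) -> str | None:
    """Merge-equivalence of a ternary norm with the binary SS/SJ family.

    Returns ``"spade"`` when merging B and N into one (bad) label leaves a
    Simple Standing / Stern Judging norm, ``"club"`` when merging N and G
    into one (good) label does, and ``None`` otherwise.
    """
    if _matches_merged_ss_sj(norm, good={G}):
        return "spade"
    if _matches_merged_ss_sj(norm, good={N, G}):
        return "club"
    return None
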