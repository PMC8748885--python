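"""Systematic sweeps of norm spaces with symmetry reduction and pruning.

Scopes:

* ``binary_full`` — all 2^8 x 2^4 = 4096 binary norms;
* ``ternary_second_order`` — the 3^6 x 2^3 = 5832 donor-independent ternary
  norms;
* ``ternary_full`` — the 3^18 x 2^9 third-order ternary space (desk scale
  only over explicit assignment sub-ranges; the full space is a cluster job);
* ``explicit_list`` — a caller-supplied list of norms.

Within a scope, one representative per reputation-permutation orbit is
evaluated (the joint lexicographic minimum of the (assignment, action)
encoding); the classical accounting that reduces assignment rules only
(64,573,605 x 512 for the ternary space) is available through
``normscan.norms.count_assignment_orbits``.

Pruning removes norms that cannot be strict Nash equilibria: whenever some
(X, Y) earns the same reputation for both actions but prescribes C, a
defector at that context is strictly better off, so the norm is skipped
before any dynamics are run.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_MU_GRID, ErrorModel, NonConvergenceError, stationary
from .ess import DEFAULT_BC_GRID, DEFAULT_PC_THRESHOLD, core_set_filter
from .norms import Norm, canonicalize, second_order_norms
from .taxonomy import (
    NotRelabelable,
    UnclassifiableNorm,
    classify,
    merge_annotation,
    relabel_by_convention,
)

__all__ = [
    "ScanConfig",
    "ScanResult",
    "SCOPES",
    "enumerate_canonical_norms",
    "prune",
    "run_scan",
    "merge_results",
    "second_order_annotations",
]

SCOPES = ("binary_full", "ternary_second_order", "ternary_full", "explicit_list")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of one norm-space sweep."""

    scope: str = "binary_full"
    k: int = 3
    err: ErrorModel = field(default_factory=ErrorModel)
    bc_grid: tuple[float, ...] = DEFAULT_BC_GRID
    p_c_threshold: float = DEFAULT_PC_THRESHOLD
    chunk_index: int = 0
    chunk_count: int = 1
    classify: bool = False
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    reduce_symmetry: bool = True
    #: for ternary_full at desk scale: half-open range of assignment integers
    assignment_range: tuple[int, int] | None = None
    #: for explicit_list
    norms: tuple[Norm, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if not (0 <= self.chunk_index < self.chunk_count):
            raise ValueError("chunk_index must lie in [0, chunk_count)")
        k = 2 if self.scope == "binary_full" else self.k
        object.__setattr__(self, "k", k)


def _scope_iter(config: ScanConfig):
    """Literal enumeration of the scope, before symmetry reduction."""
    if config.scope == "binary_full":
        for a_int in range(2**8):
            for p_int in range(2**4):
                yield Norm.from_ints(2, a_int, p_int)
    elif config.scope == "ternary_second_order":
        yield from second_order_norms(3)
    elif config.scope == "ternary_full":
        lo, hi = config.assignment_range or (0, 3**18)
        for a_int in range(lo, hi):
            for p_int in range(2**9):
                yield Norm.from_ints(3, a_int, p_int)
    elif config.scope == "explicit_list":
        yield from config.norms


def enumerate_canonical_norms(config: ScanConfig):
    """Yield exactly one representative per permutation orbit within scope,
    restricted to the configured chunk, in deterministic order.

    With ``reduce_symmetry=False`` (or for ``explicit_list``) every norm of
    the scope is yielded; chunks partition the yielded sequence round-robin,
    so the union over all ``chunk_count`` chunks is the full scope exactly
    once.
    """
    reduce_sym = config.reduce_symmetry and config.scope != "explicit_list"
    i = 0
    for norm in _scope_iter(config):
        if reduce_sym:
            rep, _ = canonicalize(norm)
            if rep != norm:
                continue
        if i % config.chunk_count == config.chunk_index:
            yield norm
        i += 1


def prune(norm: Norm) -> bool:
    """True when the norm can be skipped: some context prescribes C although
    both actions earn the same reputation, so defecting there strictly
    improves the payoff and the norm cannot be a strict Nash equilibrium."""
    same = norm.assignment[:, :, 0] == norm.assignment[:, :, 1]
    return bool(np.any(same & (norm.action == 0)))


@dataclass
class ScanResult:
    """Per-norm records and aggregate counts of one (chunk of a) sweep."""

    config: ScanConfig
    records: list[dict]
    counts: dict
    complete: bool = True

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "canonical_id",
            "h_B",
            "h_N",
            "h_G",
            "p_c",
            "cess_mask",
            "is_core",
            "class_label",
            "scaling_slope",
        ]
        df = pd.DataFrame(self.records)
        if df.empty:
            return pd.DataFrame(columns=cols)
        return df[cols].sort_values("canonical_id", kind="mergesort").reset_index(drop=True)

    def core_records(self) -> list[dict]:
        return [r for r in self.records if r["is_core"]]

    def class_counts(self) -> Counter:
        return Counter(
            r["class_label"] for r in self.records if r["is_core"] and r["class_label"]
        )

    def summary(self) -> dict:
        return {
            "scope": self.config.scope,
            "chunk": [self.config.chunk_index, self.config.chunk_count],
            "complete": self.complete,
            "counts": dict(self.counts),
            "class_counts": dict(sorted(self.class_counts().items())),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def _scan_one(norm: Norm, config: ScanConfig) -> dict:
    record = {
        "canonical_id": norm.compact_id,
        "h_B": np.nan,
        "h_N": np.nan,
        "h_G": np.nan,
        "p_c": np.nan,
        "cess_mask": 0,
        "is_core": False,
        "class_label": None,
        "scaling_slope": np.nan,
        "status": "evaluated",
    }
    try:
        stat = stationary(norm, config.err)
    except NonConvergenceError:
        record["status"] = "no_convergence"
        return record
    record["h_B"] = stat.h_B
    record["h_G"] = stat.h_G
    if norm.k == 3:
        record["h_N"] = float(stat.h_star[1])
    record["p_c"] = stat.p_c
    is_core, reports = core_set_filter(
        norm, config.bc_grid, config.err, config.p_c_threshold, stat=stat
    )
    mask = 0
    for bit, ratio in enumerate(config.bc_grid):
        if reports[ratio].is_cess:
            mask |= 1 << bit
    record["cess_mask"] = mask
    record["is_core"] = is_core
    if is_core and config.classify:
        try:
            label = classify(norm, config.err, config.mu_grid, stat=stat)
            record["class_label"] = label.label
            record["scaling_slope"] = label.scaling_slope
        except (UnclassifiableNorm, NotRelabelable) as exc:
            record["class_label"] = "unclassifiable"
            record["status"] = f"unclassifiable: {exc.args[0]}"
    return record


def run_scan(config: ScanConfig, progress: bool = False) -> ScanResult:
    """Evaluate every canonical norm of the configured chunk.

    Funnel per norm: prune -> stationary state -> cooperation-level gate ->
    mutant loop over every alternative action rule at every b/c ratio ->
    (optionally) relabel and classify the core survivors.
    """
    records: list[dict] = []
    counts = Counter(scanned=0, pruned=0, evaluated=0, passed_threshold=0, core_cess=0)
    for norm in enumerate_canonical_norms(config):
        counts["scanned"] += 1
        if prune(norm):
            counts["pruned"] += 1
            continue
        record = _scan_one(norm, config)
        counts["evaluated"] += 1
        if record["p_c"] >= config.p_c_threshold:
            counts["passed_threshold"] += 1
        if record["is_core"]:
            counts["core_cess"] += 1
        records.append(record)
        if progress and counts["scanned"] % 500 == 0:  # pragma: no cover
            print(
                f"[{config.scope} {config.chunk_index}/{config.chunk_count}] "
                f"scanned={counts['scanned']} pruned={counts['pruned']} "
                f"passed={counts['passed_threshold']} core={counts['core_cess']}"
            )
    return ScanResult(config=config, records=records, counts=dict(counts))


def merge_results(parts: list[ScanResult]) -> ScanResult:
    """Deterministic merge of the chunks of one sweep.

    Fails loudly unless the parts cover every chunk index exactly once with
    identical scan settings; partial chunk sets are never merged silently.
    """
    if not parts:
        raise ValueError("nothing to merge")
    base = parts[0].config
    expected = replace(base, chunk_index=0)
    indices = []
    for part in parts:
        if replace(part.config, chunk_index=0) != expected:
            raise ValueError("chunks come from different scan configurations")
        indices.append(part.config.chunk_index)
    if sorted(indices) != list(range(base.chunk_count)):
        missing = set(range(base.chunk_count)) - set(indices)
        raise ValueError(f"incomplete chunk set; missing {sorted(missing)}")
    records = [r for part in parts for r in part.records]
    records.sort(key=lambda r: r["canonical_id"])
    counts = Counter()
    for part in parts:
        counts.update(part.counts)
    return ScanResult(config=expected, records=records, counts=dict(counts))


def second_order_annotations(result: ScanResult) -> dict[str, str]:
    """Merge-equivalence annotations for the core CESSs of a second-order scan.

    For each core norm (in conventional labelling), reports ``"spade"`` when
    merging B and N reproduces the binary Simple Standing / Stern Judging
    family, ``"club"`` when merging N and G does, and ``"none"`` when neither
    merge is consistent or lands in the family.
    """
    if result.config.scope != "ternary_second_order":
        raise ValueError("annotations apply to ternary_second_order scans")
    out: dict[str, str] = {}
    for record in result.core_records():
        norm = Norm.from_compact_id(3, record["canonical_id"])
        conventional, _ = relabel_by_convention(norm, err=result.config.err)
        out[record["canonical_id"]] = merge_annotation(conventional) or "none"
    return out
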