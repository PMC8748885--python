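"""Packaged example norms.

Twelve conventional ternary example norms — one per C/P/R subclass — ship as
prescription-text files under ``normscan/data``; the eight binary leading
norms are constructed programmatically (:func:`normscan.norms.leading_eight`).
"""

from __future__ import annotations

from importlib import resources

from .norms import Norm, parse_norm_text

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_text", "all_fixtures"]

#: Subclass labels of the packaged examples, in taxonomy order.
FIXTURE_NAMES = (
    "c1p1r1",
    "c1p1r2",
    "c1p2r1",
    "c1p2r2",
    "c2p1r1",
    "c2p1r2",
    "c2p2r1",
    "c2p2r2",
    "c3p1r1",
    "c3p1r2",
    "c3p2r1",
    "c3p2r2",
)


def fixture_text(name: str) -> str:
    """Raw prescription text of a packaged example norm."""
    name = name.lower().replace("-", "")
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return (resources.files(__package__) / "data" / f"{name}.norm").read_text()


def load_fixture(name: str) -> Norm:
    """Parse a packaged example norm by its subclass name (e.g. ``"c1p1r1"``)."""
    return parse_norm_text(fixture_text(name))


def all_fixtures() -> dict[str, Norm]:
    """All packaged example norms keyed by subclass name."""
    return {name: load_fixture(name) for name in FIXTURE_NAMES}
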