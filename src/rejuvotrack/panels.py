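"""Bundled marker-gene panels.

Two panels ship with the package, mirroring the published marker table for
the reprogramming time course: 19 pluripotency markers (ascending; early-
and late-activation cluster hints) and 19 fibroblast-identity markers
(descending; three decline-pattern hints, with HSP47 and CD34 published
without a cluster label and therefore carrying an empty hint). Probe IDs are
Agilent expression-array accessions. Cluster hints are treated as expected
outputs for comparison, never as clustering inputs.
"""

from __future__ import annotations

from importlib import resources

from .trajectories import GenePanel, read_panel

__all__ = ["BUNDLED_PANELS", "load_bundled_panel"]

BUNDLED_PANELS = ("pluripotency", "fibroblast")


def load_bundled_panel(name: str) -> GenePanel:
    """Load one of the bundled panels by name ('pluripotency' or 'fibroblast')."""
    if name not in BUNDLED_PANELS:
        raise KeyError(f"unknown panel {name!r}; available: {BUNDLED_PANELS}")
    ref = resources.files("rejuvotrack.data") / f"{name}_panel.csv"
    with resources.as_file(ref) as path:
        return read_panel(path)
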