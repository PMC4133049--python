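"""On-disk landscape bundle: a directory holding the panel plus metadata.

Only the ±1 panel is stored; the correlation matrix, its inverse and the
couplings are deterministic functions of it and are recomputed on load, so
a reloaded bundle reproduces them bit-identically.  Optionally the
couplings are cached as .npy next to the panel for large N.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ValidationError
from .landscape import EpigeneticLandscape
from .panel import FatePanel

PANEL_FILE = "panel.tsv"
META_FILE = "meta.json"
COUPLING_CACHE = "coupling.npy"


def write_bundle(
    panel: FatePanel,
    out_dir,
    pseudo_inverse: bool = False,
    cache_coupling: bool = False,
    extra_meta: dict | None = None,
) -> EpigeneticLandscape:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape = EpigeneticLandscape(pseudo_inverse=pseudo_inverse).fit(panel)
    panel.to_tsv(out / PANEL_FILE)
    meta = {
        "tool_version": __version__,
        "n_tfs": panel.n_tfs,
        "n_fates": panel.n_fates,
        "fate_names": list(panel.fate_names),
        "condition_number": landscape.condition_number_,
        "pseudo_inverse": pseudo_inverse,
    }
    if extra_meta:
        meta.update(extra_meta)
    (out / META_FILE).write_text(json.dumps(meta, indent=2) + "\n")
    if cache_coupling:
        np.save(out / COUPLING_CACHE, landscape.coupling_)
    return landscape


def load_bundle(bundle_dir):
    """Return ``(panel, landscape, meta)`` rebuilt from a bundle directory."""
    d = Path(bundle_dir)
    if not (d / PANEL_FILE).exists():
        raise ValidationError(f"{d} is not a landscape bundle (missing {PANEL_FILE})")
    meta = json.loads((d / META_FILE).read_text()) if (d / META_FILE).exists() else {}
    panel = FatePanel.from_tsv(d / PANEL_FILE)
    landscape = EpigeneticLandscape(
        pseudo_inverse=bool(meta.get("pseudo_inverse", False))
    ).fit(panel)
    return panel, landscape, meta
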