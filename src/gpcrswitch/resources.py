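"""Paths to the packaged data files.

``reference_state_synthetic.pdb`` is a synthetic single-frame stand-in
for the agonist-bound reference structure (the scaffold in its base
geometry, generated by :func:`gpcrswitch.synthetic.reference_state`);
``residue_map.yaml`` is the matching annotation config.
"""
from __future__ import annotations

from importlib.resources import files
from pathlib import Path


def packaged_reference_path() -> Path:
    return Path(str(files("gpcrswitch").joinpath("data/reference_state_synthetic.pdb")))


def packaged_residue_map_path() -> Path:
    return Path(str(files("gpcrswitch").joinpath("data/residue_map.yaml")))
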