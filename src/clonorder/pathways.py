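"""Gene -> biological-pathway mapping.

The mapping is shipped as an editable YAML config (``data/pathways.yaml``)
covering the 19-gene AML targeted panel; genes absent from the mapping fall
back to :attr:`Pathway.OTHER`.
"""

from __future__ import annotations

import functools
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml


class Pathway(str, Enum):
    DNA_METHYLATION = "DNA_METHYLATION"
    SIGNALING = "SIGNALING"
    NPM1 = "NPM1"
    TRANSCRIPTION_FACTOR = "TRANSCRIPTION_FACTOR"
    SPLICING = "SPLICING"
    CHROMATIN = "CHROMATIN"
    TP53 = "TP53"
    OTHER = "OTHER"


def load_pathway_map(path: str | Path | None = None) -> dict[str, Pathway]:
    """Load a gene->pathway map from YAML (pathway -> list of genes).

    With ``path=None`` the packaged default panel mapping is returned.
    """
    if path is None:
        text = resources.files("clonorder").joinpath("data/pathways.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    mapping: dict[str, Pathway] = {}
    for pathway_name, genes in raw.items():
        pw = Pathway(pathway_name)
        for gene in genes or []:
            mapping[str(gene)] = pw
    return mapping


@functools.lru_cache(maxsize=1)
def default_pathway_map() -> dict[str, Pathway]:
    return load_pathway_map(None)


def pathway_of(gene: str, mapping: dict[str, Pathway] | None = None) -> Pathway:
    """Pathway for ``gene`` under ``mapping`` (default panel map if None)."""
    if mapping is None:
        mapping = default_pathway_map()
    return mapping.get(gene, Pathway.OTHER)
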