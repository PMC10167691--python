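"""Shared fixtures: tiny hand-built networks, datasets and files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from boolpath.data import CombinedDataset, OmicsLayer
from boolpath.network import SignedNetwork

GRAPHML_TWO_NODE = """<?xml version="1.0" encoding="UTF-8"?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns">
  <key id="d0" for="edge" attr.name="signal" attr.type="string"/>
  <graph id="toy" edgedefault="directed">
    <node id="A"/>
    <node id="B"/>
    <edge source="A" target="B"><data key="d0">{sign}</data></edge>
  </graph>
</graphml>
"""

#: two gene entries, one activating relation; a third gene inhibits a
#: two-member group; a compound mediates X -> cpd -> B
KGML_TOY = """<?xml version="1.0"?>
<pathway name="path:toy" title="Toy pathway" org="hsa" number="00001">
  <entry id="1" name="hsa:10" type="gene">
    <graphics name="A, ALIAS1" type="rectangle"/>
  </entry>
  <entry id="2" name="hsa:20" type="gene">
    <graphics name="B" type="rectangle"/>
  </entry>
  <entry id="3" name="hsa:30" type="gene">
    <graphics name="X" type="rectangle"/>
  </entry>
  <entry id="4" name="hsa:40" type="gene">
    <graphics name="M1" type="rectangle"/>
  </entry>
  <entry id="5" name="hsa:50" type="gene">
    <graphics name="M2" type="rectangle"/>
  </entry>
  <entry id="6" name="undefined" type="group">
    <component id="4"/>
    <component id="5"/>
  </entry>
  <entry id="7" name="cpd:C00001" type="compound">
    <graphics name="C00001" type="circle"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="3" entry2="6" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
  <relation entry1="3" entry2="7" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="7" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def graphml_activation(tmp_path):
    path = tmp_path / "act.graphml"
    path.write_text(GRAPHML_TWO_NODE.format(sign="a"))
    return path


@pytest.fixture
def graphml_inhibition(tmp_path):
    path = tmp_path / "inh.graphml"
    path.write_text(GRAPHML_TWO_NODE.format(sign="i"))
    return path


@pytest.fixture
def kgml_toy(tmp_path):
    path = tmp_path / "toy.kgml"
    path.write_text(KGML_TOY)
    return path


@pytest.fixture
def chain_network() -> SignedNetwork:
    """A -> B activation chain."""
    return SignedNetwork.from_edges("chain", ["A", "B"], [("A", "B", 1)])


def make_layer(name: str, data: dict[str, list[float]], samples: list[str]) -> OmicsLayer:
    return OmicsLayer(
        name=name,
        abundance=pd.DataFrame.from_dict(data, orient="index", columns=samples),
    )


@pytest.fixture
def two_condition_dataset() -> CombinedDataset:
    """One layer, genes A/B, two conditions x two replicates.

    A follows the condition (high in c1), B follows A.
    """
    layer = make_layer(
        "rna",
        {"A": [8.0, 8.2, 4.0, 4.1], "B": [7.9, 8.1, 4.2, 4.0]},
        ["s1", "s2", "s3", "s4"],
    )
    design = {"s1": "c1", "s2": "c1", "s3": "c0", "s4": "c0"}
    return CombinedDataset(layers=[layer], design=design)
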