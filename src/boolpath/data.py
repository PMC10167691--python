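"""Multiomics expression layers, design/contrast matrices, binarization.

Each omics layer (transcriptomics, proteomics, phosphoproteomics, ...)
is a genes x samples matrix of nonnegative log-scale abundances.  Layers
share a design (sample -> condition) and are compared through named
contrasts.  Boolean rule inference trains on binarized views of the
layers: per gene and layer, abundances above the midpoint of the
observed (min, max) range are "on".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

Transform = Literal["log2p1", "log2rpm", "none"]


@dataclass
class OmicsLayer:
    """One omics layer: a genes x samples matrix of log-scale abundances."""

    name: str
    abundance: pd.DataFrame  # genes (index) x samples (columns), values >= 0

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            raise ValueError(f"layer {self.name}: duplicate sample ids")
        if self.abundance.index.duplicated().any():
            dups = self.abundance.index[self.abundance.index.duplicated()].tolist()
            raise ValueError(f"layer {self.name}: duplicate gene rows {dups}")
        self.abundance.index = self.abundance.index.map(lambda g: str(g).strip().upper())

    @property
    def genes(self) -> set[str]:
        return set(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)


def load_layer(path: str | Path, layer_name: str, transform: Transform = "none") -> OmicsLayer:
    """Load an expression matrix from delimited text (genes x samples).

    ``transform`` is applied to the raw values:

    - ``log2p1``: log2(x + 1), the usual transform for proteomic
      intensities;
    - ``log2rpm``: log2(reads-per-million + 1) for transcriptomic counts
      (the +1 pseudocount guards zero counts, keeping values finite and
      nonnegative);
    - ``none``: values are already log-scale.

    Rows whose median raw value is 0 are discarded (genes effectively
    unobserved in half or more of the samples carry no signal).
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    non_numeric = table.columns[
        [not pd.api.types.is_numeric_dtype(table[c]) for c in table.columns]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = table[pd.to_numeric(table[col], errors="coerce").isna()].index.tolist()
            raise ValueError(
                f"{path}: non-numeric values in column {col!r}, rows {bad[:5]}"
            )
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows {dups[:5]}")

    table = table.loc[table.median(axis=1) > 0]
    values = table.astype(float)
    if transform == "log2p1":
        values = np.log2(values + 1.0)
    elif transform == "log2rpm":
        rpm = values / values.sum(axis=0) * 1e6
        values = np.log2(rpm + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return OmicsLayer(name=layer_name, abundance=values)


@dataclass
class ContrastMatrix:
    """Named comparisons between pairs of conditions."""

    contrasts: list[tuple[str, str, str]]  # (name, condition_A, condition_B)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.contrasts]
        if len(set(names)) != len(names):
            raise ValueError("contrast names must be unique")
        for name, a, b in self.contrasts:
            if a == b:
                raise ValueError(f"contrast {name}: conditions must differ")

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.contrasts)

    def __getitem__(self, name: str) -> tuple[str, str]:
        for cname, a, b in self.contrasts:
            if cname == name:
                return a, b
        raise KeyError(f"unknown contrast {name!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ContrastMatrix":
        """Read a three-column delimited file: name, condition_A, condition_B."""
        table = pd.read_csv(path, sep=None, engine="python", header=0)
        return cls([tuple(map(str, row[:3])) for row in table.itertuples(index=False)])


def load_design(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited file (sample, condition) into a mapping."""
    table = pd.read_csv(path, sep=None, engine="python", header=0)
    return {str(r[0]): str(r[1]) for r in table.itertuples(index=False)}


@dataclass
class CombinedDataset:
    """Multiomics layers sharing a design (sample -> condition).

    Conditions are assumed matched across layers; sample ids may differ
    between layers as long as every sample appears in the design.
    """

    layers: list[OmicsLayer]
    design: dict[str, str]  # sample -> condition

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        for layer in self.layers:
            missing = [s for s in layer.sample_ids if s not in self.design]
            if missing:
                raise ValueError(
                    f"layer {layer.name}: samples missing from design: {missing[:5]}"
                )

    @property
    def gene_universe(self) -> set[str]:
        universe: set[str] = set()
        for layer in self.layers:
            universe |= layer.genes
        return universe

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def conditions(self) -> set[str]:
        return set(self.design.values())

    def layer(self, name: str) -> OmicsLayer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"unknown layer {name!r}")

    def condition_samples(self, layer: OmicsLayer, condition: str) -> list[str]:
        return [s for s in layer.sample_ids if self.design[s] == condition]


@dataclass
class BinarizedStates:
    """Per (layer, sample) Boolean gene states plus measurement masks.

    ``bits[layer_name]`` is a genes x samples 0/1 DataFrame; a gene
    absent from the layer has no row (the measurement mask).  States are
    iterated as (layer, sample, gene -> bit) training constraints.
    """

    bits: dict[str, pd.DataFrame] = field(default_factory=dict)

    def measured(self, layer_name: str) -> set[str]:
        return set(self.bits[layer_name].index)

    def states(self) -> Iterator[tuple[str, str, pd.Series]]:
        for layer_name, frame in self.bits.items():
            for sample in frame.columns:
                yield layer_name, sample, frame[sample]

    @property
    def n_states(self) -> int:
        return sum(frame.shape[1] for frame in self.bits.values())


def binarize(dataset: CombinedDataset) -> BinarizedStates:
    """Threshold each gene at the midpoint of its per-layer (min, max).

    The midpoint rule is scale-robust on log data: it is invariant to
    adding a constant to all of a gene's values within a layer.
    Constant genes fall to 0 (strict inequality at the threshold).
    """
    bits: dict[str, pd.DataFrame] = {}
    for layer in dataset.layers:
        values = layer.abundance
        threshold = (values.min(axis=1) + values.max(axis=1)) / 2.0
        bits[layer.name] = values.gt(threshold, axis=0).astype(np.int8)
    return BinarizedStates(bits=bits)


def _contrast_samples(
    dataset: CombinedDataset, layer: OmicsLayer, condition: str
) -> list[str]:
    samples = dataset.condition_samples(layer, condition)
    if not samples:
        raise ValueError(
            f"layer {layer.name}: no samples for condition {condition!r}"
        )
    return samples


def fold_change(
    dataset: CombinedDataset,
    contrast: tuple[str, str],
    layer_name: str,
) -> pd.Series:
    """Per-gene log fold-change for condition_A vs condition_B in a layer.

    Computed as the difference of condition means on the log scale.
    Genes not measured in the layer get 0.  Indexed over the dataset's
    full gene universe.
    """
    cond_a, cond_b = contrast
    layer = dataset.layer(layer_name)
    samples_a = _contrast_samples(dataset, layer, cond_a)
    samples_b = _contrast_samples(dataset, layer, cond_b)
    fc = layer.abundance[samples_a].mean(axis=1) - layer.abundance[samples_b].mean(axis=1)
    return fc.reindex(sorted(dataset.gene_universe), fill_value=0.0)


def variability(
    dataset: CombinedDataset,
    contrast: tuple[str, str],
    layer_name: str,
) -> pd.Series:
    """Per-gene coefficient of variation over the contrast's samples.

    CV = sample standard deviation (n-1 denominator) / mean of the
    log-abundances pooled over both contrast conditions.  Zero-mean or
    constant genes get 0; genes not measured in the layer get 0.
    """
    cond_a, cond_b = contrast
    layer = dataset.layer(layer_name)
    samples = _contrast_samples(dataset, layer, cond_a) + _contrast_samples(
        dataset, layer, cond_b
    )
    values = layer.abundance[samples]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = sd.where(mean != 0, 0.0) / mean.replace(0, np.nan)
    cv = cv.fillna(0.0)
    return cv.reindex(sorted(dataset.gene_universe), fill_value=0.0)
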