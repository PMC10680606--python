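"""Core containers: layered regulatory networks, regulator profiles, expression matrices.

A network has three layers -- master regulators (MR), transcription factors
(TF) and target genes -- with directed edges MR->TF and TF->gene only.  Nodes
are addressed by a single global index: MRs occupy ``0..n_mr-1``, TFs
``n_mr..n_mr+n_tf-1`` and genes the remainder.  Node identifiers are derived
from the layer ("MR0", "TF3", "G17").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, ParameterError

LAYER_MR = "MR"
LAYER_TF = "TF"
LAYER_GENE = "G"


def node_id(layer: str, index_in_layer: int) -> str:
    return f"{layer}{index_in_layer}"


@dataclass
class RegulatoryNetwork:
    """Layered directed network with signed interaction strengths.

    Parameters
    ----------
    n_mr, n_tf, n_g
        Number of nodes in each layer.
    edges
        Integer array of shape ``(n_edges, 2)`` holding ``(regulator, target)``
        global node indices.  MR->TF edges come first, then TF->gene edges.
    K
        Signed interaction strengths per edge (``None`` until assigned);
        ``K < 0`` marks repression.
    hill
        Integer Hill coefficients per edge (``None`` until assigned).
    """

    n_mr: int
    n_tf: int
    n_g: int
    edges: np.ndarray
    K: np.ndarray | None = None
    hill: np.ndarray | None = None

    # ------------------------------------------------------------------ layout
    @property
    def n_nodes(self) -> int:
        return self.n_mr + self.n_tf + self.n_g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tf_slice(self) -> slice:
        return slice(self.n_mr, self.n_mr + self.n_tf)

    @property
    def gene_slice(self) -> slice:
        return slice(self.n_mr + self.n_tf, self.n_nodes)

    def layer_of(self, node: int) -> str:
        if node < self.n_mr:
            return LAYER_MR
        if node < self.n_mr + self.n_tf:
            return LAYER_TF
        return LAYER_GENE

    @property
    def node_ids(self) -> list[str]:
        ids = [node_id(LAYER_MR, i) for i in range(self.n_mr)]
        ids += [node_id(LAYER_TF, i) for i in range(self.n_tf)]
        ids += [node_id(LAYER_GENE, i) for i in range(self.n_g)]
        return ids

    @property
    def layers(self) -> list[str]:
        return (
            [LAYER_MR] * self.n_mr + [LAYER_TF] * self.n_tf + [LAYER_GENE] * self.n_g
        )

    @property
    def parameterized(self) -> bool:
        return self.K is not None and self.hill is not None

    # --------------------------------------------------------------- structure
    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def label_matrix(self) -> np.ndarray:
        """Binary ``(n_g, n_tf)`` matrix; entry 1 iff TF j regulates gene i."""
        lab = np.zeros((self.n_g, self.n_tf), dtype=np.int8)
        tf0 = self.n_mr
        g0 = self.n_mr + self.n_tf
        for reg, tgt in self.edges:
            if tgt >= g0:
                lab[tgt - g0, reg - tf0] = 1
        return lab

    def validate(self) -> None:
        """Assert the layered-topology invariants, raising on violation."""
        if self.n_mr < 1 or self.n_tf < 1 or self.n_g < 1:
            raise ParameterError("all layer sizes must be >= 1")
        e = self.edges
        if len(e) and (e.min() < 0 or e.max() >= self.n_nodes):
            raise ConsistencyError("edge endpoint out of range")
        tf0, g0 = self.n_mr, self.n_mr + self.n_tf
        for reg, tgt in e:
            rl, tl = self.layer_of(reg), self.layer_of(tgt)
            if not ((rl == LAYER_MR and tl == LAYER_TF) or (rl == LAYER_TF and tl == LAYER_GENE)):
                raise ConsistencyError(f"edge {reg}->{tgt} crosses layers {rl}->{tl}")
        pairs = {tuple(x) for x in e.tolist()}
        if len(pairs) != len(e):
            raise ConsistencyError("duplicate (regulator, target) pair")
        if self.K is not None:
            absk = np.abs(self.K)
            if absk.min() < 1.0 or absk.max() > 5.0:
                raise ConsistencyError("|K| outside [1, 5]")
        if self.hill is not None and not np.isin(self.hill, (1, 2)).all():
            raise ConsistencyError("Hill coefficient outside {1, 2}")


@dataclass
class MRProfileSet:
    """Per-condition production rates for each master regulator.

    ``rates`` has shape ``(m, n_mr)``: one row per condition ("cell type"),
    one column per MR.  ``low`` / ``high`` record the two disjoint positive
    ranges the rates were drawn from.
    """

    rates: np.ndarray
    low: tuple[float, float]
    high: tuple[float, float]

    @property
    def m(self) -> int:
        return self.rates.shape[0]

    @property
    def n_mr(self) -> int:
        return self.rates.shape[1]


@dataclass
class ExpressionMatrix:
    """Gene-by-condition expression values with row identifiers and layer tags."""

    values: np.ndarray  # (n_rows, m), nonnegative
    row_ids: list[str]
    layers: list[str]  # one of MR/TF/G per row
    condition_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.condition_ids:
            self.condition_ids = [f"c{j}" for j in range(self.values.shape[1])]
        if len(self.row_ids) != self.values.shape[0] or len(self.layers) != self.values.shape[0]:
            raise ConsistencyError("row metadata does not match matrix shape")

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError as exc:
            raise ConsistencyError(f"unknown row id {row_id!r}") from exc

    def rows_of_layer(self, layer: str) -> list[str]:
        return [r for r, l in zip(self.row_ids, self.layers) if l == layer]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.row_ids), list(self.layers), list(self.condition_ids)
        )
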