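"""Baum-Ragan matrix representation of a curated source-tree collection.

Every nontrivial, non-root clade of every source tree becomes one binary
"group inclusion" character: taxa inside the clade score 1, taxa elsewhere in
the same tree score 0, and taxa absent from that tree score "?". A synthetic
all-zero outgroup row roots the subsequent parsimony analysis. Character
weights are inherited from the source-tree analysis weights and kept as exact
rationals; they are scaled to integers only when the matrix is serialised
(TNT or NEXUS).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .curation import Dataset
from .tree import TreeNode

__all__ = ["MRPMatrix", "EmptyMatrixError", "encode_brs", "write_matrix", "read_matrix",
           "DEFAULT_OUTGROUP"]

DEFAULT_OUTGROUP = "MRP_Outgroup"

MISSING = np.int8(-1)  # matrix code for "?"


class EmptyMatrixError(ValueError):
    """Raised when a dataset yields no group-inclusion characters."""


@dataclass(frozen=True)
class MRPMatrix:
    """Taxa x binary-character matrix with weights and provenance.

    ``data[i, j]`` is 0, 1 or -1 ("?") for taxon ``taxa[i]`` and character
    ``j``. The outgroup row is all zero. Provenance records, per character,
    the study key and the pre-order index of the source-tree node it encodes.
    """

    taxa: tuple[str, ...]
    data: np.ndarray  # int8, shape (ntaxa, nchar)
    weights: tuple[Fraction, ...]
    outgroup: str
    provenance: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self):
        if self.data.shape != (len(self.taxa), len(self.weights)):
            raise ValueError("matrix shape does not match taxa/weights")
        og = self.taxa.index(self.outgroup)
        if not np.all(self.data[og] == 0):
            raise ValueError("outgroup row must be all zero")
        nonmissing = self.data != MISSING
        ones = ((self.data == 1) & nonmissing).sum(axis=0)
        zeros = ((self.data == 0) & nonmissing).sum(axis=0)
        if self.n_characters and (ones.min() < 2 or zeros.min() < 1):
            raise ValueError("every character needs >=2 ones and >=1 zero")
        if any(w <= 0 for w in self.weights):
            raise ValueError("character weights must be positive")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    @property
    def weight_sum(self) -> Fraction:
        return sum(self.weights, Fraction(0))

    def integer_weights(self) -> tuple[tuple[int, ...], int]:
        """Weights scaled by the LCM of their denominators; returns
        (integer weights, scale factor)."""
        scale = math.lcm(*(w.denominator for w in self.weights)) if self.weights else 1
        return tuple(int(w * scale) for w in self.weights), scale

    def proportional_to(self, other: "MRPMatrix") -> bool:
        """True if taxa and characters match and weights agree up to a
        positive rational scale (serialisation scales weights to integers)."""
        if self.taxa != other.taxa or not np.array_equal(self.data, other.data):
            return False
        if self.n_characters == 0:
            return True
        ratio = other.weights[0] / self.weights[0]
        return ratio > 0 and all(
            b == a * ratio for a, b in zip(self.weights, other.weights)
        )


def encode_brs(dataset: Dataset, outgroup_name: str = DEFAULT_OUTGROUP) -> MRPMatrix:
    """Encode a curated dataset as a Baum-Ragan MRP matrix.

    One character per nontrivial non-root clade of each source tree, in
    record order and then pre-order within each tree. The root node of a
    source tree yields no character: against the all-zero outgroup it would
    be uninformative.

    Raises
    ------
    EmptyMatrixError
        If no source tree contributes a character (e.g. all stars).
    ValueError
        If the outgroup name collides with a real taxon.
    """
    all_taxa = sorted(dataset.taxa())
    if outgroup_name in all_taxa:
        raise ValueError(f"outgroup name {outgroup_name!r} collides with a real taxon")
    taxa = (outgroup_name, *all_taxa)
    index = {t: i for i, t in enumerate(taxa)}

    columns: list[np.ndarray] = []
    weights: list[Fraction] = []
    provenance: list[tuple[str, int]] = []
    for rec in dataset.records:
        tree = rec.tree
        # pre-order numbering over all nodes of this tree
        order: list[TreeNode] = []
        stack = [tree.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        present = rec.taxa
        for node_id, node in enumerate(order):
            if node.is_leaf or node is tree.root:
                continue
            members = node.leaf_labels()
            if len(members) < 2 or len(members) >= len(present):
                continue
            col = np.full(len(taxa), MISSING, dtype=np.int8)
            for t in present:
                col[index[t]] = 1 if t in members else 0
            col[0] = 0  # outgroup
            columns.append(col)
            weights.append(rec.weight)
            provenance.append((rec.study_key, node_id))
    if not columns:
        raise EmptyMatrixError("empty matrix: no informative clades in the dataset")
    data = np.stack(columns, axis=1)
    return MRPMatrix(taxa, data, tuple(weights), outgroup_name, tuple(provenance))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_LABEL_SAFE = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _check_labels(matrix: MRPMatrix, fmt: str) -> None:
    for t in matrix.taxa:
        if not _LABEL_SAFE.match(t):
            raise ValueError(f"taxon label not serialisable in {fmt}: {t!r}")


def _rows(matrix: MRPMatrix) -> list[str]:
    width = max(len(t) for t in matrix.taxa) + 2
    out = []
    for i, t in enumerate(matrix.taxa):
        states = "".join("?" if v == MISSING else str(v) for v in matrix.data[i])
        out.append(f"{t:<{width}}{states}")
    return out


def write_matrix(matrix: MRPMatrix, format: str = "tnt") -> str:
    """Serialise to TNT (``xread`` + ``ccode`` weights) or NEXUS (DATA block
    + ASSUMPTIONS WTSET). Rational weights are scaled to integers by the LCM
    of their denominators."""
    if format not in ("tnt", "nexus"):
        raise ValueError(f"unknown matrix format: {format}")
    _check_labels(matrix, format)
    int_weights, _ = matrix.integer_weights()
    if format == "tnt":
        lines = [
            "xread",
            f"'MRP matrix: {matrix.n_characters} characters, {matrix.n_taxa} taxa'",
            f"{matrix.n_characters} {matrix.n_taxa}",
        ]
        lines += _rows(matrix)
        lines.append(";")
        by_weight: dict[int, list[int]] = {}
        for j, w in enumerate(int_weights):
            by_weight.setdefault(w, []).append(j)
        for w in sorted(by_weight):
            chars = " ".join(str(j) for j in by_weight[w])
            lines.append(f"ccode /{w} {chars};")
        lines.append("proc /;")
        return "\n".join(lines) + "\n"

    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    MATRIX",
    ]
    lines += ["        " + r for r in _rows(matrix)]
    lines += ["    ;", "END;", "BEGIN ASSUMPTIONS;"]
    by_weight = {}
    for j, w in enumerate(int_weights):
        by_weight.setdefault(w, []).append(j)
    parts = []
    for w in sorted(by_weight):
        chars = " ".join(str(j + 1) for j in by_weight[w])  # NEXUS is 1-based
        parts.append(f"{w}: {chars}")
    lines.append(f"    WTSET * mrp = {', '.join(parts)};")
    lines += ["END;"]
    return "\n".join(lines) + "\n"


def _parse_rows(row_lines: list[str]) -> tuple[list[str], np.ndarray]:
    taxa, cols = [], []
    for line in row_lines:
        name, states = line.split(None, 1)
        states = states.strip()
        taxa.append(name)
        cols.append([MISSING if c == "?" else np.int8(int(c)) for c in states])
    return taxa, np.array(cols, dtype=np.int8)


def read_matrix(text: str, format: str = "tnt") -> MRPMatrix:
    """Parse a matrix written by :func:`write_matrix`.

    The outgroup is identified as the unique all-zero row (the first such row
    if several). Weights come back as the serialised integers; they equal the
    original rationals up to one positive scale factor
    (see :meth:`MRPMatrix.proportional_to`).
    """
    if format == "tnt":
        body = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)\s*(.*?);", text, re.S)
        if not body:
            raise ValueError("not a TNT xread matrix")
        nchar, ntax = int(body.group(1)), int(body.group(2))
        rows = [ln for ln in body.group(3).strip().splitlines() if ln.strip()]
        taxa, data = _parse_rows(rows)
        weights = [Fraction(1)] * nchar
        for m in re.finditer(r"ccode\s*/(\d+)\s+([\d\s]+);", text):
            w = Fraction(int(m.group(1)))
            for j in m.group(2).split():
                weights[int(j)] = w
    elif format == "nexus":
        body = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I)
        if not body:
            raise ValueError("not a NEXUS DATA matrix")
        rows = [ln for ln in body.group(1).strip().splitlines() if ln.strip()]
        taxa, data = _parse_rows(rows)
        nchar = data.shape[1]
        weights = [Fraction(1)] * nchar
        wt = re.search(r"WTSET\s*\*?\s*\w+\s*=\s*([^;]+);", text, re.I)
        if wt:
            for part in wt.group(1).split(","):
                w_str, chars = part.split(":")
                for j in chars.split():
                    weights[int(j) - 1] = Fraction(int(w_str))
    else:
        raise ValueError(f"unknown matrix format: {format}")
    if data.shape[0] != len(taxa):
        raise ValueError("row count mismatch")
    zero_rows = [t for i, t in enumerate(taxa) if np.all(data[i] == 0)]
    if not zero_rows:
        raise ValueError("no all-zero outgroup row found")
    return MRPMatrix(tuple(taxa), data, tuple(weights), zero_rows[0])
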