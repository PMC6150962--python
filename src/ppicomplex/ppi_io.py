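"""Reading and writing PPI edge lists and protein-complex set files.

Networks are held as :class:`networkx.Graph` objects over opaque, case-sensitive
protein-ID strings.  Edge lists are the common 2-3 column dialect (two IDs and
an optional numeric weight, tab or space delimited; ``#`` comments and blank
lines ignored).  Complex sets are one complex per line, members whitespace
separated.  Reading canonicalizes: self-loops are dropped and duplicate pairs
(in either orientation) collapse to a single undirected edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Complex",
    "read_edge_list",
    "write_edge_list",
    "read_complexes",
    "write_complexes",
]


@dataclass(frozen=True)
class Complex:
    """A protein complex: a set of >=2 protein IDs, optionally labelled/scored.

    ``label`` is one of ``"positive"``, ``"intermediate"``, ``"negative"`` when
    the complex is part of a training set; ``score`` carries the detector's
    regression score for candidate complexes.
    """

    members: frozenset = field()
    label: Optional[str] = None
    score: Optional[float] = None

    def __init__(self, members: Iterable[str], label: Optional[str] = None,
                 score: Optional[float] = None):
        object.__setattr__(self, "members", frozenset(members))
        if label is not None and label not in ("positive", "intermediate", "negative"):
            raise ValueError(f"invalid complex label: {label!r}")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "score", score)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def sorted_members(self) -> list:
        return sorted(self.members)


def _tokenize(line: str, delimiter: str) -> list:
    if delimiter == "tab":
        return [t for t in line.rstrip("\n").split("\t") if t != ""]
    # "space" and "auto" both split on arbitrary whitespace, which also
    # handles tab-delimited files, so "auto" needs no sniffing.
    return line.split()


def read_edge_list(path, delimiter: str = "auto") -> nx.Graph:
    """Read a 2-3 column PPI edge list into a canonical undirected graph.

    Duplicated pairs (either orientation) are collapsed keeping the first
    occurrence's weight; self-interactions are dropped.  A third numeric
    column is stored as the ``weight`` edge attribute.

    Raises
    ------
    ValueError
        On a line with a single token, or a non-numeric third column.
    """
    if delimiter not in ("auto", "tab", "space"):
        raise ValueError(f"unknown delimiter mode: {delimiter!r}")
    path = Path(path)
    net = nx.Graph()
    n_dups = n_selfloops = 0
    warned_extra_cols = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _tokenize(raw, delimiter)
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed edge line (needs >=2 columns): {line!r}"
                )
            u, v = tokens[0], tokens[1]
            weight = None
            if len(tokens) >= 3:
                try:
                    weight = float(tokens[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: third column is not numeric: {tokens[2]!r}"
                    ) from None
                if len(tokens) > 3 and not warned_extra_cols:
                    warnings.warn(
                        f"{path}: columns beyond the third are ignored "
                        f"(first seen at line {lineno})"
                    )
                    warned_extra_cols = True
            if u == v:
                n_selfloops += 1
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                n_dups += 1
                continue
            if weight is None:
                net.add_edge(u, v)
            else:
                net.add_edge(u, v, weight=weight)
    if net.number_of_nodes() == 0:
        warnings.warn(f"{path}: empty edge list")
    if n_dups or n_selfloops:
        logger.info(
            "read %s: %d nodes, %d edges (%d duplicate pairs collapsed, %d self-loops dropped)",
            path, net.number_of_nodes(), net.number_of_edges(), n_dups, n_selfloops,
        )
    return net


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a canonical edge list, endpoints lexicographically ordered per line.

    A weight column is emitted iff any edge carries a ``weight`` attribute
    (edges lacking one are written with weight 1.0, with a warning).
    """
    path = Path(path)
    weighted = any("weight" in d for _, _, d in net.edges(data=True))
    if weighted and not all("weight" in d for _, _, d in net.edges(data=True)):
        warnings.warn("network mixes weighted and unweighted edges; "
                      "missing weights written as 1.0")
    lines = []
    for u, v, data in net.edges(data=True):
        a, b = (u, v) if u <= v else (v, u)
        if weighted:
            w = data.get("weight", 1.0)
            lines.append((a, b, f"{a}\t{b}\t{float(w)!r}"))
        else:
            lines.append((a, b, f"{a}\t{b}"))
    lines.sort()
    with path.open("w") as fh:
        for _, _, line in lines:
            fh.write(line + "\n")


def read_complexes(path) -> list:
    """Read a complex-set file: one complex per line, members whitespace split.

    Duplicate members within a line collapse; lines with fewer than two
    distinct members are skipped with a warning.
    """
    path = Path(path)
    complexes = []
    n_skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members = frozenset(line.split())
            if len(members) < 2:
                n_skipped += 1
                warnings.warn(
                    f"{path}:{lineno}: complex with <2 distinct members skipped"
                )
                continue
            complexes.append(Complex(members))
    if not complexes:
        warnings.warn(f"{path}: no complexes read")
    if n_skipped:
        logger.info("read %s: %d complexes (%d undersized lines skipped)",
                    path, len(complexes), n_skipped)
    return complexes


def write_complexes(complexes: Iterable[Complex], path) -> None:
    """Write complexes one per line, members sorted lexicographically."""
    path = Path(path)
    with path.open("w") as fh:
        for cx in complexes:
            fh.write(" ".join(sorted(cx.members)) + "\n")
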