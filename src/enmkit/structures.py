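"""Coarse-grained structure handling: Cα node sets read from PDB text.

An elastic network model consumes only the Cα trace of one chain of one
model: coordinates, author residue numbers (which may contain gaps where
disordered segments are missing from the crystal structure), insertion
codes, chain ID and residue names. This module extracts that node set,
repairs residue-number gaps by contiguous re-indexing, and maps author
residue-number ranges onto node-index domain segments.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import EmptySelectionError, PdbParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSet",
    "DomainAnnotation",
    "parse_structure",
    "reindex_contiguous",
    "assign_domains",
    "write_pdb",
    "nodes_to_table",
    "nodes_from_table",
]


@dataclass
class NodeSet:
    """Ordered Cα nodes of one chain: the network the ENM is built on.

    ``node_index`` is always the contiguous positional index 0..N-1;
    ``residue_numbers`` keeps the author numbering (gaps allowed) for
    reporting. ``gap_table`` records (last_resnum_before, first_resnum_after,
    gap_size) for each numbering gap found by :func:`reindex_contiguous`.
    """

    coords: np.ndarray                      # (N, 3) float, Å
    residue_numbers: np.ndarray             # (N,) int, author numbering
    chain_ids: list[str]
    residue_names: list[str]
    insertion_codes: list[str] = field(default_factory=list)
    gap_table: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if not self.insertion_codes:
            self.insertion_codes = [""] * len(self.residue_numbers)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def node_index(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def validate(self) -> None:
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"coords must be (N, 3), got {self.coords.shape}")
        if n < 2:
            raise ValidationError(f"a node set needs N >= 2 nodes, got {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")
        for name, seq in (
            ("residue_numbers", self.residue_numbers),
            ("chain_ids", self.chain_ids),
            ("residue_names", self.residue_names),
            ("insertion_codes", self.insertion_codes),
        ):
            if len(seq) != n:
                raise ValidationError(
                    f"{name} has length {len(seq)}, expected {n}"
                )

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """(chain, resSeq, iCode) identity per node, for residue pairing."""
        return [
            (c, int(r), i)
            for c, r, i in zip(
                self.chain_ids, self.residue_numbers, self.insertion_codes
            )
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NodeSet":
        """Return a copy with coordinates rigidly transformed (x -> R x + t)."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=new)


@dataclass
class DomainAnnotation:
    """Ordered, non-overlapping node-index segments with labels.

    Segments are (label, start_node_index, end_node_index), ends inclusive.
    """

    segments: list[tuple[str, int, int]]
    n_nodes: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for label, start, end in self.segments:
            if not (0 <= start <= end < self.n_nodes):
                raise ValidationError(
                    f"segment {label!r} [{start}, {end}] outside 0..{self.n_nodes - 1}"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"segment {label!r} starting at {start} overlaps or is "
                    f"unsorted relative to previous segment ending at {prev_end}"
                )
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [seg[0] for seg in self.segments]

    def segment_indices(self, label: str) -> np.ndarray:
        for lab, start, end in self.segments:
            if lab == label:
                return np.arange(start, end + 1)
        raise KeyError(label)


def _model_by_number(structure, model: int):
    models = list(structure.get_models())
    for m in models:
        if m.serial_num == model:
            return m
    if 1 <= model <= len(models):
        return models[model - 1]
    return None


def parse_structure(pdb_text: str, chain: str = "A", model: int = 1) -> NodeSet:
    """Extract the Cα node set of one chain/model from PDB-format text.

    One node per residue carrying a CA atom, in file order. HETATM records
    and non-CA atoms are ignored. For alternate locations the highest-
    occupancy CA is kept (ties: first listed — Biopython's selection rule).
    Residues without a CA are skipped with a logged warning, mirroring how
    disordered segments are simply absent from crystal structures.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("input", io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise PdbParseError(f"malformed PDB record: {exc}") from exc

    mod = _model_by_number(structure, model)
    if mod is None:
        raise EmptySelectionError(
            f"model {model} not present in input (found "
            f"{len(list(structure.get_models()))} model(s))"
        )
    if chain not in [c.id for c in mod]:
        raise EmptySelectionError(
            f"no CA atoms selected: chain {chain!r} absent from model {model}"
        )

    coords, resnums, icodes, resnames, chains = [], [], [], [], []
    for residue in mod[chain]:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # HETATM (waters, ligands) are never network nodes
        if "CA" not in residue:
            logger.warning(
                "residue %s %d%s in chain %s has no CA atom; skipped",
                residue.resname, resseq, icode.strip(), chain,
            )
            continue
        ca = residue["CA"]  # DisorderedAtom resolves to highest occupancy
        coords.append(ca.get_coord())
        resnums.append(resseq)
        icodes.append(icode.strip())
        resnames.append(residue.resname)
        chains.append(chain)

    if not coords:
        raise EmptySelectionError(
            f"no CA atoms selected in chain {chain!r}, model {model}"
        )
    if len(coords) < 2:
        raise EmptySelectionError(
            f"only {len(coords)} CA atom in chain {chain!r}, model {model}; "
            "a network needs at least 2 nodes"
        )
    return NodeSet(
        coords=np.array(coords, dtype=float),
        residue_numbers=np.array(resnums, dtype=int),
        chain_ids=chains,
        residue_names=resnames,
        insertion_codes=icodes,
    )


def reindex_contiguous(nodes: NodeSet) -> NodeSet:
    """Record residue-number gaps and return nodes under contiguous indexing.

    Node identity is positional (0..N-1) regardless of author numbering, so
    numbering gaps — e.g. a disordered linker absent from the coordinates —
    do not perturb the network. Original residue numbers are preserved for
    reporting; the gap table lists (before, after, size) per gap within a
    chain. Idempotent.
    """
    gaps: list[tuple[int, int, int]] = []
    resnums = nodes.residue_numbers
    for i in range(1, nodes.n_nodes):
        if nodes.chain_ids[i] != nodes.chain_ids[i - 1]:
            continue
        step = int(resnums[i]) - int(resnums[i - 1])
        if step > 1:
            gaps.append((int(resnums[i - 1]), int(resnums[i]), step - 1))
    if gaps:
        logger.info("re-indexed over %d residue-number gap(s): %s", len(gaps), gaps)
    return replace(nodes, gap_table=gaps)


def assign_domains(
    nodes: NodeSet,
    ranges: list[tuple[str, int, int]],
) -> DomainAnnotation:
    """Map author residue-number ranges onto node-index domain segments.

    Ranges are (label, start_residue_number, end_residue_number), inclusive,
    in author numbering. Residues not covered by any range are collected into
    ``unassigned`` segments. Ranges referencing absent residue numbers are
    clipped to the residues present (logged); overlapping ranges are an error.
    """
    labels = [r[0] for r in ranges]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"domain labels must be unique, got {labels}")

    assigned = np.full(nodes.n_nodes, -1, dtype=int)
    resnums = nodes.residue_numbers
    for k, (label, lo, hi) in enumerate(ranges):
        if lo > hi:
            raise ValidationError(f"range {label!r} has start {lo} > end {hi}")
        mask = (resnums >= lo) & (resnums <= hi)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            logger.warning(
                "range %r [%d, %d] matches no residues; skipped", label, lo, hi
            )
            continue
        clash = assigned[idx] >= 0
        if np.any(clash):
            other = ranges[assigned[idx[clash][0]]][0]
            raise ValidationError(
                f"ranges {other!r} and {label!r} overlap at residue "
                f"{int(resnums[idx[clash][0]])}"
            )
        if int(resnums[idx[0]]) != lo or int(resnums[idx[-1]]) != hi:
            logger.warning(
                "range %r [%d, %d] clipped to present residues [%d, %d]",
                label, lo, hi, int(resnums[idx[0]]), int(resnums[idx[-1]]),
            )
        assigned[idx] = k

    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, nodes.n_nodes + 1):
        if i == nodes.n_nodes or assigned[i] != assigned[start]:
            label = "unassigned" if assigned[start] < 0 else ranges[assigned[start]][0]
            segments.append((label, start, i - 1))
            start = i
    return DomainAnnotation(segments=segments, n_nodes=nodes.n_nodes)


# ---------------------------------------------------------------------------
# Tabular and PDB round trips

_TABLE_COLUMNS = [
    "node_index", "chain", "resSeq", "iCode", "resName", "x", "y", "z"
]


def nodes_to_table(nodes: NodeSet) -> pd.DataFrame:
    """Internal tabular dump of the node set (TSV-friendly)."""
    return pd.DataFrame(
        {
            "node_index": nodes.node_index,
            "chain": nodes.chain_ids,
            "resSeq": nodes.residue_numbers,
            "iCode": nodes.insertion_codes,
            "resName": nodes.residue_names,
            "x": nodes.coords[:, 0],
            "y": nodes.coords[:, 1],
            "z": nodes.coords[:, 2],
        },
        columns=_TABLE_COLUMNS,
    )


def nodes_from_table(table: pd.DataFrame) -> NodeSet:
    """Rebuild a NodeSet from :func:`nodes_to_table` output (lossless)."""
    icodes = ["" if pd.isna(v) else str(v) for v in table["iCode"]]
    return NodeSet(
        coords=table[["x", "y", "z"]].to_numpy(dtype=float),
        residue_numbers=table["resSeq"].to_numpy(dtype=int),
        chain_ids=[str(c) for c in table["chain"]],
        residue_names=[str(r) for r in table["resName"]],
        insertion_codes=icodes,
    )


def write_pdb(nodes: NodeSet, path, bfactors: np.ndarray | None = None) -> None:
    """Write the node set as a minimal CA-only PDB file.

    ``bfactors`` (one value per node) fills the B-factor column — the
    standard trick for color-by-value in any molecular viewer.
    """
    if bfactors is None:
        bfactors = np.zeros(nodes.n_nodes)
    bfactors = np.asarray(bfactors, dtype=float)
    if bfactors.shape != (nodes.n_nodes,):
        raise ValidationError(
            f"bfactors must have shape ({nodes.n_nodes},), got {bfactors.shape}"
        )
    lines = []
    for i in range(nodes.n_nodes):
        x, y, z = nodes.coords[i]
        icode = nodes.insertion_codes[i] or " "
        lines.append(
            f"ATOM  {i + 1:>5}  CA  {nodes.residue_names[i]:>3} "
            f"{nodes.chain_ids[i]:1}{int(nodes.residue_numbers[i]):>4}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactors[i]:6.2f}"
            f"          {'C':>2}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
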