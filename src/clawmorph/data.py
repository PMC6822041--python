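"""Core domain types and file I/O.

Landmark layout
---------------
Every claw configuration carries 83 ordered planar points:

========  =========  ====================================
indices   count      meaning
========  =========  ====================================
1-6       6          fixed landmarks LM1-LM6
7-19      13         SL1, dorsal bony core (LM1 -> LM4)
20-37     18         SL2, ventral bony core (LM3 -> LM4)
38-65     28         SL3, dorsal keratinous sheath (LM1 -> LM6)
66-83     18         SL4, ventral keratinous sheath (LM5 -> LM6)
========  =========  ====================================

Indices above (and in all user-facing messages) are 1-based; arrays are
0-based internally.  The default core/sheath partition is
core = {1,2,3,4} u {7..37}, sheath = {5,6} u {38..83}.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import MalformedRecordError, TPSParseError, TreeError, ValidationError

N_LANDMARKS = 83
N_FIXED = 6
CURVE_NAMES = ("SL1", "SL2", "SL3", "SL4")
CURVE_SIZES = {"SL1": 13, "SL2": 18, "SL3": 28, "SL4": 18}

# 0-based half-open slices of each semilandmark curve in canonical order
CURVE_SLICES = {
    "SL1": slice(6, 19),
    "SL2": slice(19, 37),
    "SL3": slice(37, 65),
    "SL4": slice(65, 83),
}
# fixed-landmark anchors (0-based) at the start/end of each curve
CURVE_ANCHORS = {
    "SL1": (0, 3),   # LM1 -> LM4
    "SL2": (2, 3),   # LM3 -> LM4
    "SL3": (0, 5),   # LM1 -> LM6
    "SL4": (4, 5),   # LM5 -> LM6
}


class Ecology(str, Enum):
    PREDATORY = "predatory"
    GROUND = "ground"
    FLYING = "flying"
    UNKNOWN = "unknown"


def point_roles() -> list[str]:
    """Role of each of the 83 points, canonical order."""
    return ["fixed"] * N_FIXED + ["semilandmark"] * (N_LANDMARKS - N_FIXED)


def point_curve_ids() -> list[str]:
    """Curve membership ('none' for fixed landmarks), canonical order."""
    ids = ["none"] * N_FIXED
    for name in CURVE_NAMES:
        ids += [name] * CURVE_SIZES[name]
    return ids


@dataclass
class ClawConfiguration:
    """One specimen's 83 ordered 2D landmarks."""

    specimen_id: str
    coords: np.ndarray  # (83, 2)
    species: str = ""
    ecology: Ecology = Ecology.UNKNOWN
    scale: float = 1.0
    roles: list[str] = field(default_factory=point_roles)
    curve_id: list[str] = field(default_factory=point_curve_ids)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if isinstance(self.ecology, str) and not isinstance(self.ecology, Ecology):
            self.ecology = Ecology(self.ecology)
        self.validate()

    def validate(self) -> None:
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: expected {N_LANDMARKS} points, "
                f"got array of shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: scale must be positive"
            )
        if self.roles != point_roles() or self.curve_id != point_curve_ids():
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-canonical role/curve annotations"
            )

    def curve(self, name: str) -> np.ndarray:
        return self.coords[CURVE_SLICES[name]]

    def with_coords(self, coords: np.ndarray) -> "ClawConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class LandmarkPartition:
    """Disjoint index sets (1-based) splitting the 83 points into two modules."""

    core_indices: frozenset[int]
    sheath_indices: frozenset[int]

    def __post_init__(self):
        if self.core_indices & self.sheath_indices:
            raise ValidationError("partition subsets overlap")
        if self.core_indices | self.sheath_indices != set(range(1, N_LANDMARKS + 1)):
            raise ValidationError("partition must cover landmarks 1..83 exactly")

    @classmethod
    def default(cls) -> "LandmarkPartition":
        core = frozenset({1, 2, 3, 4} | set(range(7, 38)))
        sheath = frozenset({5, 6} | set(range(38, 84)))
        return cls(core, sheath)

    def core_array(self) -> np.ndarray:
        """0-based sorted index array for the core module."""
        return np.array(sorted(i - 1 for i in self.core_indices))

    def sheath_array(self) -> np.ndarray:
        return np.array(sorted(i - 1 for i in self.sheath_indices))


class Phylogeny:
    """Rooted tree with branch lengths over uniquely named tips.

    Thin wrapper around a dendropy tree; construction validates tip-name
    uniqueness and branch-length presence/finiteness.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip names: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge length may be absent
            if edge.length is None:
                head = edge.head_node
                name = (
                    head.taxon.label
                    if head.taxon is not None
                    else f"internal node with {len(head.leaf_nodes())} descendant tips"
                )
                raise TreeError(f"missing branch length on edge above {name!r}")
            if not np.isfinite(edge.length) or edge.length < 0:
                raise TreeError(f"invalid branch length {edge.length!r}")
        self.tips: list[str] = sorted(labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def __len__(self) -> int:
        return len(self.tips)

    def node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = node.edge.length or 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()
        }

    def covariance(self, species: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """C[i, j] = shared root-to-MRCA path length; diagonal = tip depths."""
        order = list(species) if species is not None else self.tips
        unknown = [s for s in order if s not in set(self.tips)]
        if unknown:
            raise TreeError(f"species not in tree: {unknown}")
        idx = {name: i for i, name in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        depths = self.node_depths()
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                if label in idx:
                    C[idx[label], idx[label]] = depths[node]
                continue
            children = node.child_nodes()
            groups = []
            for child in children:
                tips_in = [
                    idx[l.taxon.label]
                    for l in child.leaf_iter()
                    if l.taxon.label in idx
                ]
                groups.append(tips_in)
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = d
                            C[j, i] = d
        return C, order

    def write_newick(self, path: str | Path) -> None:
        text = self._tree.as_string(schema="newick", suppress_rooting=True)
        Path(path).write_text(text)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

_KEYVAL = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def _parse_coord(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TPSParseError(f"expected 'x y' coordinate pair, got {line!r}", lineno)
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise TPSParseError(f"non-numeric coordinate in {line!r}", lineno) from None


def read_tps(path: str | Path) -> list[ClawConfiguration]:
    """Read a TPS landmark file into claw configurations.

    Two dialects are supported: flat ``LM=83`` records carrying all points
    in canonical order, and ``LM=6`` records followed by ``CURVES=4`` /
    ``POINTS=`` blocks (curve order SL1..SL4) which are flattened into
    canonical order.  ``SCALE=`` is applied multiplicatively; ``ID=`` or
    ``IMAGE=`` becomes the specimen id.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[ClawConfiguration] = []
    i = 0
    n_lines = len(lines)

    def next_record_start(j):
        while j < n_lines and not lines[j].strip():
            j += 1
        return j

    i = next_record_start(i)
    while i < n_lines:
        m = _KEYVAL.match(lines[i])
        if not m or m.group(1).upper() != "LM":
            raise TPSParseError(f"expected LM= record header, got {lines[i]!r}", i + 1)
        record_line = i + 1
        try:
            lm_count = int(m.group(2))
        except ValueError:
            raise TPSParseError(f"bad LM count {m.group(2)!r}", i + 1) from None
        i += 1
        fixed = []
        for _ in range(lm_count):
            if i >= n_lines:
                raise MalformedRecordError(
                    f"record at line {record_line}: truncated coordinate block"
                )
            fixed.append(_parse_coord(lines[i], i + 1))
            i += 1
        curves: list[list[tuple[float, float]]] = []
        scale = None
        spec_id = None
        image = None
        while i < n_lines and lines[i].strip():
            m = _KEYVAL.match(lines[i])
            if m is None:
                raise TPSParseError(f"unexpected content {lines[i]!r}", i + 1)
            key = m.group(1).upper()
            if key == "LM":
                break  # next record
            if key == "CURVES":
                n_curves = int(m.group(2))
                i += 1
                for _ in range(n_curves):
                    pm = _KEYVAL.match(lines[i]) if i < n_lines else None
                    if pm is None or pm.group(1).upper() != "POINTS":
                        raise TPSParseError("expected POINTS= after CURVES=", i + 1)
                    npts = int(pm.group(2))
                    i += 1
                    pts = []
                    for _ in range(npts):
                        pts.append(_parse_coord(lines[i], i + 1))
                        i += 1
                    curves.append(pts)
            elif key == "SCALE":
                scale = float(m.group(2))
                i += 1
            elif key == "ID":
                spec_id = m.group(2)
                i += 1
            elif key == "IMAGE":
                image = m.group(2)
                i += 1
            else:  # tolerated metadata (e.g. COMMENT=)
                i += 1

        if curves:
            sizes = [len(c) for c in curves]
            expected = [CURVE_SIZES[n] for n in CURVE_NAMES]
            if lm_count != N_FIXED or sizes != expected:
                raise MalformedRecordError(
                    f"record at line {record_line}: expected LM={N_FIXED} with curve "
                    f"sizes {expected}, got LM={lm_count} with {sizes}"
                )
            pts = fixed + [p for c in curves for p in c]
        else:
            if lm_count != N_LANDMARKS:
                raise MalformedRecordError(
                    f"record at line {record_line}: expected LM={N_LANDMARKS} "
                    f"(or LM={N_FIXED} with curves), got LM={lm_count}"
                )
            pts = fixed
        coords = np.array(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        name = spec_id if spec_id is not None else (image or f"record_{len(configs) + 1}")
        configs.append(
            ClawConfiguration(
                specimen_id=name, coords=coords, scale=scale if scale else 1.0
            )
        )
        i = next_record_start(i)
    return configs


def write_tps(configs: Sequence[ClawConfiguration], path: str | Path) -> None:
    """Write configurations as flat LM=83 TPS records (dialect a)."""
    buf = _io.StringIO()
    for cfg in configs:
        cfg.validate()
        buf.write(f"LM={N_LANDMARKS}\n")
        raw = cfg.coords / cfg.scale
        for x, y in raw:
            buf.write(f"{x:.17g} {y:.17g}\n")
        if cfg.scale != 1.0:
            buf.write(f"SCALE={cfg.scale:.17g}\n")
        buf.write(f"ID={cfg.specimen_id}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Newick I/O and pruning
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> Phylogeny:
    """Read a single rooted Newick tree with branch lengths."""
    s = str(path_or_string)
    if "(" in s and ";" in s:
        data = s
    else:
        data = Path(path_or_string).read_text()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"could not parse newick: {exc}") from exc
    return Phylogeny(tree)


def prune_tree(phylo: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune to `keep`, collapsing unifurcations and summing branch lengths."""
    keep = sorted(set(keep))
    if not keep:
        raise TreeError("cannot prune to an empty tip set")
    unknown = [k for k in keep if k not in set(phylo.tips)]
    if unknown:
        raise TreeError(f"species not in tree: {unknown}")
    sub = phylo.tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    # extract_tree drops the collapsed root edge in some dendropy versions;
    # restore root-to-tip depths by adjusting the root edge length.
    pruned = Phylogeny(sub)
    orig = phylo.tip_depths()
    new = pruned.tip_depths()
    delta = orig[keep[0]] - new[keep[0]]
    if abs(delta) > 1e-12:
        root = sub.seed_node
        root.edge.length = (root.edge.length or 0.0) + delta
        pruned = Phylogeny(sub)
    return pruned


# ---------------------------------------------------------------------------
# Metadata and species means
# ---------------------------------------------------------------------------

@dataclass
class MetadataTable:
    """Specimen metadata: one row per specimen_id with species and ecology."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"specimen_id", "species", "ecology"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        ids = self.table["specimen_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        valid = {e.value for e in Ecology}
        bad = set(self.table["ecology"]) - valid
        if bad:
            raise ValidationError(f"unknown ecology labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path: str | Path) -> "MetadataTable":
        return cls(pd.read_csv(path, dtype=str))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def species_of(self, specimen_id: str) -> str:
        row = self.table.loc[self.table["specimen_id"] == specimen_id]
        if row.empty:
            raise ValidationError(f"specimen {specimen_id!r} not in metadata")
        return row["species"].iloc[0]

    def species_ecology(self) -> pd.Series:
        """Unique ecology per species; raises on conflicting labels."""
        grouped = self.table.groupby("species")["ecology"].agg(set)
        conflicts = grouped[grouped.map(len) > 1]
        if not conflicts.empty:
            raise ValidationError(
                f"conflicting ecology labels for species: {list(conflicts.index)}"
            )
        return grouped.map(lambda s: next(iter(s)))


def attach_metadata(
    configs: Sequence[ClawConfiguration], metadata: MetadataTable
) -> list[ClawConfiguration]:
    """Return configurations with species/ecology filled from the metadata."""
    lut = metadata.table.set_index("specimen_id")
    out = []
    for cfg in configs:
        if cfg.specimen_id not in lut.index:
            raise ValidationError(f"specimen {cfg.specimen_id!r} not in metadata")
        row = lut.loc[cfg.specimen_id]
        out.append(
            replace(cfg, species=row["species"], ecology=Ecology(row["ecology"]))
        )
    return out


def species_means(
    values: pd.DataFrame | np.ndarray,
    metadata: MetadataTable,
    specimen_ids: Sequence[str] | None = None,
    log_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Average per-specimen values to per-species means.

    `values` is either a DataFrame indexed (or keyed by a 'specimen_id'
    column) per specimen, or a raw array with `specimen_ids` giving row
    order.  Averaging happens on the raw scale; columns named in
    `log_columns` are log-transformed *after* averaging (the convention
    used for centroid size).  The species ecology column is carried along.
    """
    if isinstance(values, np.ndarray):
        if specimen_ids is None:
            raise ValidationError("specimen_ids required with array input")
        df = pd.DataFrame(values, index=list(specimen_ids))
    else:
        df = values.copy()
        if "specimen_id" in df.columns:
            df = df.set_index("specimen_id")
    lut = metadata.table.set_index("specimen_id")["species"]
    missing = [s for s in df.index if s not in lut.index]
    if missing:
        raise ValidationError(f"specimens without metadata: {missing}")
    species = df.index.map(lut)
    out = df.groupby(species, sort=True).mean()
    for col in log_columns:
        out[col] = np.log(out[col])
    eco = metadata.species_ecology()
    out["ecology"] = eco.reindex(out.index)
    out.index.name = "species"
    return out
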