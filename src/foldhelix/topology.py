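"""Residue templates and chain topology for (mQQ)n aromatic oligoamide helices.

A foldamer chain alternates aminomethyl-quinoline (mQ) and quinoline (Q)
residues; one mQQ repeat unit (two consecutive residues) plays the geometric
role of one base pair in the DNA mimic. Templates map residue names to the
atom groups every downstream geometry operation consumes: the aromatic ring
atoms (whose geometric center traces the helix), side-chain/phosphonate
atoms, hydrogen-bond donors/acceptors, and the six backbone dihedral
quadruples conventionally labelled alpha..zeta along one repeat unit.

Atom quadruples are configuration, not chemistry hard-coded here: real
force-field atom naming varies between setups. The built-in templates are
defined against the pseudo-atom chemistry of :mod:`foldhelix.synthetic`
(ring atoms ``C1..Cm``, backbone atoms ``N1..Nm``, phosphonate
``P/O1-O3/H1``) and are flagged as assumptions in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DIHEDRAL_LABELS",
    "ResidueTemplate",
    "ResidueInstance",
    "FoldamerTopology",
    "TemplateError",
    "TopologyError",
    "builtin_registry",
    "load_templates",
    "build_topology",
]

#: Canonical dihedral labels along one mQQ repeat unit (ASCII spellings of
#: the Greek letters used in the field).
DIHEDRAL_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")

_GREEK_ALIASES = {
    "α": "alpha", "β": "beta", "γ": "gamma",
    "δ": "delta", "ε": "epsilon", "ζ": "zeta",
}


class TemplateError(ValueError):
    """Raised for malformed or inconsistent residue-template configuration."""


class TopologyError(ValueError):
    """Raised when a chain topology cannot be built from a frame."""


@dataclass(frozen=True)
class ResidueTemplate:
    """Atom-group definitions for one residue type.

    ``dihedral_defs`` maps a label in :data:`DIHEDRAL_LABELS` to a quadruple
    of ``(atom_name, residue_offset)`` pairs, offsets in {-1, 0, +1}
    relative to the residue the template is attached to.
    """

    name: str
    ring_atoms: tuple[str, ...]
    side_chain_atoms: tuple[str, ...] = ()
    phosphorus_atom: str | None = None
    hbond_donor_hydrogens: tuple[str, ...] = ()
    hbond_acceptor_oxygens: tuple[str, ...] = ()
    dihedral_defs: Mapping[str, tuple[tuple[str, int], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if len(self.ring_atoms) < 6:
            raise TemplateError(
                f"template {self.name!r}: ring_atoms needs >= 6 atoms, "
                f"got {len(self.ring_atoms)}"
            )
        seen = set()
        for label, quad in self.dihedral_defs.items():
            if label not in DIHEDRAL_LABELS:
                raise TemplateError(
                    f"template {self.name!r}: unknown dihedral label {label!r}"
                )
            if label in seen:
                raise TemplateError(
                    f"template {self.name!r}: duplicate dihedral label {label!r}"
                )
            seen.add(label)
            if len(quad) != 4:
                raise TemplateError(
                    f"template {self.name!r}: dihedral {label!r} needs exactly "
                    f"4 atoms, got {len(quad)}"
                )
            for atom, off in quad:
                if off not in (-1, 0, 1):
                    raise TemplateError(
                        f"template {self.name!r}: dihedral {label!r} atom "
                        f"{atom!r} has offset {off} outside -1..+1"
                    )


@dataclass
class ResidueInstance:
    """One residue of a built chain: template plus resolved atom indices."""

    index: int
    name: str
    template: ResidueTemplate
    atom_indices: dict[str, int]

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom_indices[n] for n in names], dtype=np.intp)


class TemplateRegistry(dict):
    """Mapping residue name -> :class:`ResidueTemplate`."""

    def add(self, template: ResidueTemplate, replace: bool = False):
        if template.name in self and not replace:
            raise TemplateError(f"duplicate template name {template.name!r}")
        self[template.name] = template


def _pseudo_atom_names(m: int):
    ring = tuple(f"C{i + 1}" for i in range(m))
    backbone = tuple(f"N{i + 1}" for i in range(m))
    return ring, backbone


def _builtin_dihedral_defs():
    # Quadruples span the two residues of one unit (offsets 0 = mQ, +1 = Q).
    # gamma and delta terminate on dedicated probe atoms (N4, N5 of the Q
    # residue) that appear in no other quadruple, so a controlled rotation of
    # that single atom shifts exactly one dihedral.
    return {
        "alpha": (("C2", 0), ("C1", 0), ("N1", 0), ("N2", 0)),
        "beta": (("C3", 0), ("C2", 0), ("C1", 0), ("N3", 0)),
        "gamma": (("C1", 0), ("N1", 0), ("C1", 1), ("N4", 1)),
        "delta": (("N1", 0), ("C1", 1), ("N1", 1), ("N5", 1)),
        "epsilon": (("C2", 0), ("C1", 0), ("C1", 1), ("C2", 1)),
        "zeta": (("C3", 0), ("C1", 0), ("N1", 1), ("C4", 1)),
    }


def builtin_registry(atoms_per_ring: int = 6) -> TemplateRegistry:
    """Built-in templates for mQ, Q4, Q5, mQOMe and B in pseudo-atom naming.

    The mQ template carries all six alpha..zeta quadruples of the repeat
    unit; Q-type templates carry none (the unit is analyzed through its mQ
    member). B is an inert chiral unit: it participates in the sequence and
    the coarse-grained axis but defines no dihedrals.
    """
    ring, backbone = _pseudo_atom_names(atoms_per_ring)
    phos = dict(
        side_chain_atoms=("P", "O1", "O2", "O3", "H1"),
        phosphorus_atom="P",
        hbond_donor_hydrogens=("H1",),
        hbond_acceptor_oxygens=("O1", "O2", "O3"),
    )
    reg = TemplateRegistry()
    reg.add(
        ResidueTemplate(
            name="mQ",
            ring_atoms=ring + backbone[:0],  # ring proper
            side_chain_atoms=phos["side_chain_atoms"],
            phosphorus_atom="P",
            hbond_donor_hydrogens=("H1",),
            hbond_acceptor_oxygens=("O1", "O2", "O3"),
            dihedral_defs=_builtin_dihedral_defs(),
        )
    )
    for qname in ("Q4", "Q5"):
        reg.add(ResidueTemplate(name=qname, ring_atoms=ring, **phos))
    reg.add(ResidueTemplate(name="mQOMe", ring_atoms=ring))
    reg.add(ResidueTemplate(name="B", ring_atoms=ring))
    return reg


def _parse_quad(label, raw):
    if not isinstance(raw, (list, tuple)) or len(raw) != 4:
        raise TemplateError(
            f"dihedral {label!r}: expected a list of 4 'ATOM@OFFSET' entries"
        )
    quad = []
    for entry in raw:
        try:
            if "@" in str(entry):
                atom, off = str(entry).split("@")
                quad.append((atom.strip(), int(off)))
            else:
                quad.append((str(entry).strip(), 0))
        except (ValueError, TypeError) as exc:
            raise TemplateError(
                f"dihedral {label!r}: malformed atom entry {entry!r}"
            ) from exc
    return tuple(quad)


def load_templates(source: str | None = None) -> TemplateRegistry:
    """Parse a YAML template document and merge it over the built-ins.

    ``source`` is YAML text or a path to a YAML file; ``None`` or an empty
    document yields the built-in registry unchanged. Each top-level key is a
    residue name; dihedral quadruples use ``ATOM@OFFSET`` syntax, e.g.
    ``gamma: [C1@0, N1@0, C1@+1, N4@+1]``. Greek one-letter labels are
    accepted as aliases.
    """
    reg = builtin_registry()
    if source is None:
        return reg
    text = source
    try:
        import os

        if os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
    except (TypeError, ValueError):
        pass
    doc = yaml.safe_load(text)
    if doc is None:
        return reg
    if not isinstance(doc, dict):
        raise TemplateError("template document must be a mapping of residue names")
    for name, body in doc.items():
        if not isinstance(body, dict):
            raise TemplateError(f"template {name!r}: body must be a mapping")
        dihedrals = {}
        for label, raw in (body.get("dihedrals") or {}).items():
            label = _GREEK_ALIASES.get(str(label), str(label))
            dihedrals[label] = _parse_quad(label, raw)
        tmpl = ResidueTemplate(
            name=str(name),
            ring_atoms=tuple(body.get("ring_atoms", ())),
            side_chain_atoms=tuple(body.get("side_chain_atoms", ())),
            phosphorus_atom=body.get("phosphorus_atom"),
            hbond_donor_hydrogens=tuple(body.get("hbond_donor_hydrogens", ())),
            hbond_acceptor_oxygens=tuple(body.get("hbond_acceptor_oxygens", ())),
            dihedral_defs=dihedrals,
        )
        reg.add(tmpl, replace=name in builtin_registry())
    return reg


def _is_hydrogen(atom_name: str) -> bool:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper() == "H"
    return False


@dataclass
class FoldamerTopology:
    """Per-chain topology: residues, repeat units, and atom masks.

    Residues, units and (downstream) axis centers/steps are indexed 0-based
    half-open internally; human-facing reports convert to 1-based.
    """

    residues: list[ResidueInstance]
    units: list[tuple[int, int]]
    n_atoms: int
    heavy_atom_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_units(self) -> int:
        return len(self.units)

    # ---- atom selections -------------------------------------------------
    def ring_indices(self) -> list[np.ndarray]:
        """Per-residue indices of the aromatic ring atoms."""
        return [r.indices(r.template.ring_atoms) for r in self.residues]

    def axis_selection_indices(self, selection: str = "backbone+ring"):
        """Per-residue heavy-atom indices used for the coarse-grained axis.

        ``backbone+ring`` (default) excludes side-chain heavy atoms, which
        would otherwise contaminate the axis with side-chain flexing;
        ``all-heavy`` reproduces the literal "heavy atoms of consecutive
        units" wording.
        """
        if selection not in ("backbone+ring", "all-heavy"):
            raise ValueError(f"unknown axis selection {selection!r}")
        out = []
        for r in self.residues:
            side = set(r.template.side_chain_atoms)
            idx = [
                i
                for name, i in r.atom_indices.items()
                if self.heavy_atom_mask[i]
                and (selection == "all-heavy" or name not in side)
            ]
            out.append(np.array(sorted(idx), dtype=np.intp))
        return out

    def phosphonate_groups(self):
        """Residue-attached phosphonate groups present in this chain."""
        groups = []
        for r in self.residues:
            t = r.template
            if t.phosphorus_atom and t.phosphorus_atom in r.atom_indices:
                groups.append(
                    dict(
                        residue=r.index,
                        P=r.atom_indices[t.phosphorus_atom],
                        donors=[
                            r.atom_indices[h]
                            for h in t.hbond_donor_hydrogens
                            if h in r.atom_indices
                        ],
                        acceptors=[
                            r.atom_indices[o]
                            for o in t.hbond_acceptor_oxygens
                            if o in r.atom_indices
                        ],
                    )
                )
        return groups

    # ---- dihedral resolution ---------------------------------------------
    def dihedral_labels(self) -> tuple[str, ...]:
        labels = []
        for r in self.residues:
            for lab in r.template.dihedral_defs:
                if lab not in labels:
                    labels.append(lab)
        return tuple(sorted(labels, key=DIHEDRAL_LABELS.index))

    def dihedral_index_table(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Resolve dihedral quadruples per unit.

        Returns the label tuple and an integer array (n_units, n_labels, 4);
        unresolvable quadruples (template absent, atom missing, or offset
        leaving the chain) are marked with -1.
        """
        labels = self.dihedral_labels()
        table = np.full((self.n_units, len(labels), 4), -1, dtype=np.intp)
        for u, (ri, _) in enumerate(self.units):
            base = self.residues[ri]
            for li, lab in enumerate(labels):
                quad = base.template.dihedral_defs.get(lab)
                if quad is None:
                    continue
                idx = []
                for atom, off in quad:
                    target = ri + off
                    if not (0 <= target < self.n_residues):
                        break
                    res = self.residues[target]
                    if atom not in res.atom_indices:
                        break
                    idx.append(res.atom_indices[atom])
                else:
                    table[u, li] = idx
        return labels, table


def build_topology(
    sequence: Sequence[str],
    registry: Mapping[str, ResidueTemplate],
    frame,
    pair_units: bool = True,
) -> FoldamerTopology:
    """Build a :class:`FoldamerTopology` for ``sequence`` against ``frame``.

    ``frame`` supplies per-atom names and residue indices; atoms of residue
    ``r`` are those whose frame resid equals ``r``. Units pair residues
    (2i, 2i+1), 0-based, preserving sequence order.
    """
    names = list(sequence)
    for n in names:
        if n not in registry:
            raise TopologyError(f"residue name {n!r} not in template registry")
    if pair_units and len(names) % 2:
        raise TopologyError(
            f"unit pairing requires an even residue count, got {len(names)}"
        )
    resids = np.asarray(frame.resids)
    atom_names = list(frame.atom_names)
    n_res = int(resids.max()) + 1 if len(resids) else 0
    if n_res != len(names):
        raise TopologyError(
            f"frame has {n_res} residues but sequence has {len(names)}"
        )
    residues = []
    for r, name in enumerate(names):
        tmpl = registry[name]
        atom_map = {
            atom_names[i]: int(i) for i in np.flatnonzero(resids == r)
        }
        for ring_atom in tmpl.ring_atoms:
            if ring_atom not in atom_map:
                raise TopologyError(
                    f"residue {r} ({name}): ring atom {ring_atom!r} not found"
                )
        residues.append(
            ResidueInstance(index=r, name=name, template=tmpl, atom_indices=atom_map)
        )
    seen = np.zeros(len(atom_names), dtype=bool)
    for res in residues:
        for i in res.atom_indices.values():
            if seen[i]:
                raise TopologyError(f"atom index {i} assigned to two residues")
            seen[i] = True
    units = (
        [(2 * i, 2 * i + 1) for i in range(len(names) // 2)] if pair_units else []
    )
    heavy = np.array([not _is_hydrogen(n) for n in atom_names], dtype=bool)
    return FoldamerTopology(
        residues=residues,
        units=units,
        n_atoms=len(atom_names),
        heavy_atom_mask=heavy,
    )
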