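"""Structure input/output for capsid assemblies.

Reads PDB and mmCIF files into a light-weight residue-level representation
(one main-chain centroid per residue, plus a side-chain centroid where the
residue has side-chain heavy atoms), expands biological assemblies from
their stored transforms, applies optional structural decimation, and writes
partitions and reports in plain-text formats (TSV, JSON, PDB with domain
labels in the B-factor column).
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("capsid_domains")

#: atoms counted as main chain; everything else heavy is side chain
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: alphabet used when inventing chain ids for generated structures
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclass(frozen=True)
class AssemblyTransform:
    """A rigid-body operator (proper rotation + translation, Å) used to
    generate assembly copies from an asymmetric unit."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise StructureError(
                f"assembly rotation determinant {np.linalg.det(rot):.8f} != +1"
            )

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=1e-9)
            and np.allclose(self.translation, 0.0, atol=1e-9)
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CapsidStructure:
    """Residue-level view of a (possibly expanded) capsid assembly.

    Residues are stored in global 0-based order.  ``side_coords`` rows are
    NaN for residues without side-chain heavy atoms (glycine, or missing
    atoms in the deposited model).  ``protein_ids`` group chains/copies that
    form one coat protein; by default a protein is one chain of one assembly
    copy.
    """

    chain_ids: list[str]
    protein_ids: list[str]
    res_numbers: list[str]  # author residue number + insertion code
    res_names: list[str]
    main_coords: np.ndarray  # (N, 3) Å
    side_coords: np.ndarray  # (N, 3) Å, NaN where absent
    subdomains: dict[tuple[str, str], np.ndarray] | None = None
    _proteins: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.main_coords = np.asarray(self.main_coords, dtype=float).reshape(-1, 3)
        self.side_coords = np.asarray(self.side_coords, dtype=float).reshape(-1, 3)
        n = self.n_residues
        if not (
            len(self.chain_ids) == len(self.protein_ids) == len(self.res_numbers)
            == len(self.res_names) == len(self.side_coords) == n
        ):
            raise StructureError("inconsistent residue record lengths")
        if not np.all(np.isfinite(self.main_coords)):
            raise StructureError("non-finite main-chain coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.main_coords)

    @property
    def proteins(self) -> dict[str, np.ndarray]:
        """Map protein id -> ordered residue index array."""
        if self._proteins is None:
            order: dict[str, list[int]] = {}
            for i, pid in enumerate(self.protein_ids):
                order.setdefault(pid, []).append(i)
            self._proteins = {p: np.asarray(ix, dtype=int) for p, ix in order.items()}
        return self._proteins

    @property
    def has_side(self) -> np.ndarray:
        """Boolean mask of residues with a side-chain centroid."""
        return np.isfinite(self.side_coords).all(axis=1)

    def subset(self, indices: np.ndarray) -> "CapsidStructure":
        """New structure restricted to ``indices`` (kept in the given order)."""
        idx = np.asarray(indices, dtype=int)
        return CapsidStructure(
            chain_ids=[self.chain_ids[i] for i in idx],
            protein_ids=[self.protein_ids[i] for i in idx],
            res_numbers=[self.res_numbers[i] for i in idx],
            res_names=[self.res_names[i] for i in idx],
            main_coords=self.main_coords[idx].copy(),
            side_coords=self.side_coords[idx].copy(),
        )

    def extract_protein(self, protein_id: str) -> "CapsidStructure":
        if protein_id not in self.proteins:
            raise StructureError(f"unknown protein id {protein_id!r}")
        return self.subset(self.proteins[protein_id])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _is_amino_acid(residue: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(residue.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue: accept if it looks like a polymer amino acid
    names = {a.name for a in residue}
    return {"N", "CA", "C"} <= names


def _residue_records(residue: gemmi.Residue):
    """(main centroid, side centroid or None) for one amino-acid residue."""
    ca = residue.find_atom("CA", "*")
    if ca is None:
        return None
    side = []
    for atom in residue:
        if atom.is_hydrogen() or atom.name in BACKBONE_ATOMS:
            continue
        side.append([atom.pos.x, atom.pos.y, atom.pos.z])
    main = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    side_c = np.mean(side, axis=0) if side else None
    return main, side_c


def _assembly_transforms(st: gemmi.Structure) -> dict[str, list[AssemblyTransform]]:
    """Chain id -> list of transforms from the first stored assembly."""
    out: dict[str, list[AssemblyTransform]] = {}
    if not st.assemblies:
        return out
    assembly = st.assemblies[0]
    for gen in assembly.generators:
        chains = list(gen.chains) or [ch.name for ch in st[0]]
        ops = []
        for op in gen.operators:
            rot = np.array(op.transform.mat.tolist(), dtype=float)
            vec = np.array(op.transform.vec.tolist(), dtype=float)
            ops.append(AssemblyTransform(rot, vec))
        for ch in chains:
            out.setdefault(ch, []).extend(ops)
    return out


def load_structure(path, expand_assembly: bool = True) -> CapsidStructure:
    """Read a PDB or mmCIF file into a :class:`CapsidStructure`.

    Amino-acid residues (including HETATM amino acids such as MSE) are kept;
    waters, ligands and nucleic acids are ignored.  Residues without an
    alpha-carbon are dropped with a warning.  If ``expand_assembly`` is true
    and the file stores biological-assembly transforms (REMARK 350 BIOMT or
    the mmCIF equivalent), every copy is generated with a distinct protein
    id; a file without transforms is assumed to be pre-expanded.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")

    chain_ids: list[str] = []
    protein_ids: list[str] = []
    res_numbers: list[str] = []
    res_names: list[str] = []
    mains: list[np.ndarray] = []
    sides: list[np.ndarray] = []
    n_dropped = 0

    model = st[0]
    per_chain: dict[str, dict] = {}
    for chain in model:
        recs = {"num": [], "name": [], "main": [], "side": []}
        for residue in chain:
            if not _is_amino_acid(residue):
                continue
            rec = _residue_records(residue)
            if rec is None:
                n_dropped += 1
                continue
            main, side = rec
            num = f"{residue.seqid.num}{residue.seqid.icode}".strip()
            recs["num"].append(num)
            recs["name"].append(residue.name)
            recs["main"].append(main)
            recs["side"].append(side if side is not None else np.full(3, np.nan))
        if recs["num"]:
            if chain.name in per_chain:  # merge split chains with same name
                for k in recs:
                    per_chain[chain.name][k].extend(recs[k])
            else:
                per_chain[chain.name] = recs
    if n_dropped:
        logger.warning("dropped %d residues lacking an alpha-carbon", n_dropped)
    if not per_chain:
        raise StructureError(f"no amino-acid residues with CA found in {path}")

    transforms = _assembly_transforms(st) if expand_assembly else {}
    if expand_assembly and not transforms:
        logger.info(
            "expansion requested but no assembly transforms found in %s; "
            "assuming the file is already a full assembly", path,
        )

    for ch, recs in per_chain.items():
        main = np.asarray(recs["main"])
        side = np.asarray(recs["side"])
        ops = transforms.get(ch, [])
        if not ops:
            copies = [(ch, main, side)]
        else:
            copies = []
            for k, op in enumerate(ops):
                pid = ch if (op.is_identity and len(ops) == 1) else f"{ch}.{k + 1}"
                copies.append((pid, op.apply(main), op.apply(side)))
        for pid, mc, sc in copies:
            n = len(mc)
            chain_ids.extend([ch] * n)
            protein_ids.extend([pid] * n)
            res_numbers.extend(recs["num"])
            res_names.extend(recs["name"])
            mains.append(mc)
            sides.append(sc)

    return CapsidStructure(
        chain_ids=chain_ids,
        protein_ids=protein_ids,
        res_numbers=res_numbers,
        res_names=res_names,
        main_coords=np.concatenate(mains),
        side_coords=np.concatenate(sides),
    )


def group_chains_into_proteins(
    structure: CapsidStructure, mapping: dict[str, str]
) -> CapsidStructure:
    """Relabel protein ids, merging several chains/segments into one coat
    protein (``mapping``: old protein id -> new protein id)."""
    new_ids = [mapping.get(pid, pid) for pid in structure.protein_ids]
    return replace(structure, protein_ids=new_ids, _proteins=None)


def read_subdomain_ranges(path, structure: CapsidStructure) -> dict[tuple[str, str], np.ndarray]:
    """Read a TSV of subdomain definitions: columns ``protein``, ``subdomain``,
    ``first``, ``last`` (author residue numbers, inclusive).  Returns the
    (protein id, subdomain name) -> residue index map."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "subdomain", "first", "last"}
    if not required <= set(table.columns):
        raise StructureError(f"subdomain table must have columns {sorted(required)}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for _, row in table.iterrows():
        pid = row["protein"]
        if pid not in structure.proteins:
            raise StructureError(f"subdomain table references unknown protein {pid!r}")
        idx = structure.proteins[pid]
        nums = [structure.res_numbers[i] for i in idx]
        lo, hi = int(row["first"]), int(row["last"])

        def _num(s: str) -> int:
            return int("".join(c for c in s if c.isdigit() or c == "-"))

        member = idx[[lo <= _num(n) <= hi for n in nums]]
        key = (pid, row["subdomain"])
        out[key] = np.concatenate([out[key], member]) if key in out else member
    return out


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def decimate(structure: CapsidStructure, factor: int) -> CapsidStructure:
    """Keep every ``factor``-th residue of each protein (positions 0, factor,
    2·factor, ... in sequence order).  Side-chain centroids are dropped: the
    decimated model is meant for the single-centroid network backend with a
    correspondingly rescaled cutoff."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return structure
    shortest = min(len(ix) for ix in structure.proteins.values())
    if factor > shortest:
        raise ValueError(
            f"decimation factor {factor} exceeds shortest protein length {shortest}"
        )
    keep = np.concatenate(
        [ix[::factor] for ix in structure.proteins.values()]
    )
    keep.sort()
    out = structure.subset(keep)
    out.side_coords = np.full_like(out.main_coords, np.nan)
    return out


# ---------------------------------------------------------------------------
# partitions on disk
# ---------------------------------------------------------------------------

def _partition_frame(structure: CapsidStructure, labels: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": structure.chain_ids,
            "resnum": structure.res_numbers,
            "protein": structure.protein_ids,
            "domain": np.asarray(labels, dtype=int),
        }
    )


def write_partition(structure: CapsidStructure, partition, path, format: str = "tsv") -> None:
    """Write a partition as ``tsv`` (one residue per line), ``json`` (full
    record) or ``pdb-bfactor`` (CA trace with the domain id in the B-factor
    column, for coloring in molecular viewers)."""
    labels = np.asarray(getattr(partition, "labels", partition), dtype=int)
    if len(labels) != structure.n_residues:
        raise ValueError(
            f"partition has {len(labels)} labels for {structure.n_residues} residues"
        )
    if format == "tsv":
        _partition_frame(structure, labels).to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {
            "n_residues": structure.n_residues,
            "Q": int(len(np.unique(labels))),
            "residues": _partition_frame(structure, labels).to_dict(orient="list"),
        }
        for attr in ("total_strain", "seed", "restarts"):
            if hasattr(partition, attr):
                val = getattr(partition, attr)
                payload[attr] = None if val is None else float(val)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "pdb-bfactor":
        write_structure_pdb(structure, path, bfactors=labels)
    else:
        raise ValueError(f"unknown partition format {format!r}")


def read_partition(path, structure: CapsidStructure) -> np.ndarray:
    """Read a TSV written by :func:`write_partition` (rows may be shuffled)
    and return labels aligned to the structure's residue order."""
    table = pd.read_csv(path, sep="\t", dtype={"chain": str, "resnum": str, "protein": str})
    key_of = {}
    for _, row in table.iterrows():
        key_of[(row["protein"], row["chain"], row["resnum"])] = int(row["domain"])
    labels = np.empty(structure.n_residues, dtype=int)
    missing = []
    for i in range(structure.n_residues):
        key = (structure.protein_ids[i], structure.chain_ids[i], structure.res_numbers[i])
        if key in key_of:
            labels[i] = key_of[key]
        else:
            missing.append(key)
    if missing:
        raise ValueError(f"partition file does not cover residues: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    return labels


def write_structure_pdb(structure: CapsidStructure, path, bfactors=None) -> None:
    """Write a CA-trace PDB of the structure (one atom per residue).

    Chain ids are re-used as stored; expanded assemblies therefore repeat
    chain letters across copies, which PDB viewers tolerate for coloring.
    """
    st = gemmi.Structure()
    st.name = "capsid-domains"
    model = gemmi.Model("1")
    b = np.zeros(structure.n_residues) if bfactors is None else np.asarray(bfactors, float)
    chain = None
    prev = None
    for i in range(structure.n_residues):
        cid = structure.chain_ids[i][:2]
        if (cid, structure.protein_ids[i]) != prev:
            if chain is not None:
                model.add_chain(chain)
            chain = gemmi.Chain(cid)
            prev = (cid, structure.protein_ids[i])
        res = gemmi.Residue()
        res.name = structure.res_names[i]
        num = structure.res_numbers[i]
        digits = "".join(c for c in num if c.isdigit() or c == "-")
        res.seqid = gemmi.SeqId(int(digits) if digits else i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*structure.main_coords[i])
        atom.b_iso = float(b[i])
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    if chain is not None:
        model.add_chain(chain)
    st.add_model(model)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
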