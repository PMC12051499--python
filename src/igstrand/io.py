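"""Reading and writing macromolecular structures and numbered outputs.

Parsing is delegated to gemmi (PDB and mmCIF); this module normalizes the
result into the package's internal :class:`~igstrand.model.StructureModel`:
polymer amino-acid residues only, first model of multi-model files, one
conformer per atom (highest occupancy, ties broken by the alphabetically
first altloc), nonstandard residues kept as ``X`` when they carry a CA atom.

Numbered domains are exported as TSV, JSON, or as a PDB file with the igs#
written into the B-factor column (igs#/100, e.g. 35.53 for 3553) for
visualization.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi

from .model import STANDARD_AA, AtomRecord, Chain, Residue, StructureModel


class StructureParseError(ValueError):
    pass


class EmptyStructureError(StructureParseError):
    pass


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


def _one_letter(resname: str) -> str:
    if resname in _THREE_TO_ONE:
        return _THREE_TO_ONE[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        return one if one in STANDARD_AA else "X"
    return "X"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to the alphabetically first altloc."""
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or ""))[0]


def read_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a StructureModel.

    ``fmt`` is one of ``pdb``, ``mmcif``, ``auto`` (by extension/content).
    Only polymer amino-acid residues are kept; waters, ligands and nucleic
    acids are dropped.  Raises :class:`EmptyStructureError` when no polymer
    amino-acid content remains.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]  # first model only

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = gres.name in _THREE_TO_ONE or (info is not None and info.is_amino_acid())
            if not is_aa:
                continue
            aa = _one_letter(gres.name)
            # altloc resolution per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in by_name:
                atom = _pick_altloc(by_name[name])
                atoms.append(
                    AtomRecord(
                        name=name,
                        element=atom.element.name,
                        coord=[atom.pos.x, atom.pos.y, atom.pos.z],
                    )
                )
            if aa == "X" and not any(a.name == "CA" for a in atoms):
                continue  # nonstandard residues pass through only with a CA
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(Residue(gchain.name, gres.seqid.num, icode, aa, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer amino-acid content")
    return StructureModel(path.stem, chains)


def model_to_gemmi(model: StructureModel, bfactors: dict | None = None) -> gemmi.Structure:
    """Rebuild a gemmi Structure (single model) from the internal model."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            for a in res.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = 1.0
                atom.b_iso = float(bfactors.get(res.key, 0.0)) if bfactors else 0.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    return st


def write_pdb(model: StructureModel, path: str | Path, bfactors: dict | None = None) -> None:
    st = model_to_gemmi(model, bfactors=bfactors)
    st.setup_entities()
    st.write_pdb(str(path))


TSV_COLUMNS = [
    "structure_id",
    "chain",
    "seq_num",
    "icode",
    "aa",
    "igs_number",
    "strand_letter",
    "domain_index",
    "template_id",
    "ig_type",
]


def _numbering_rows(model: StructureModel, numbering) -> list[dict]:
    keys = {r.key for r in model.residues()}
    rows = []
    for di, dom in enumerate(numbering):
        for key in dom.hit.residues:
            if key not in keys:
                raise ValueError(f"numbered residue {key} absent from model {model.id!r}")
            res = model.residue(key)
            num = dom.numbers.get(key)
            strand = dom.strand_of.get(key)
            rows.append(
                {
                    "structure_id": model.id,
                    "chain": key[0],
                    "seq_num": key[1],
                    "icode": key[2] or "",
                    "aa": res.aa,
                    "igs_number": "NA" if num is None else num,
                    "strand_letter": strand if strand else "NA",
                    "domain_index": di,
                    "template_id": dom.hit.template_id,
                    "ig_type": dom.hit.ig_type,
                }
            )
    return rows


def write_numbered_output(
    model: StructureModel,
    numbering,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Export per-residue reference numbers.

    ``fmt``: ``tsv`` (tab-separated with header), ``json`` (same rows), or
    ``pdb_bfactor`` (igs#/100 in the B-factor column; residues without a
    number get B = 0).
    """
    path = Path(path)
    if fmt == "tsv":
        rows = _numbering_rows(model, numbering)
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in TSV_COLUMNS) + "\n")
    elif fmt == "json":
        rows = _numbering_rows(model, numbering)
        with open(path, "w") as fh:
            json.dump({"structure_id": model.id, "residues": rows}, fh, indent=1)
    elif fmt == "pdb_bfactor":
        bfac = {}
        for dom in numbering:
            for key, num in dom.numbers.items():
                if num is not None:
                    bfac[key] = num / 100.0
        write_pdb(model, path, bfactors=bfac)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_numbered_tsv(path: str | Path) -> list[dict]:
    """Parse a TSV written by :func:`write_numbered_output` back into rows."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected TSV header in {path}")
        rows = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rows.append(dict(zip(header, vals)))
    return rows
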