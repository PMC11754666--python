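"""Reading and writing atomic structures; duplex selection and validation.

PDB and mmCIF files are parsed with gemmi. Base pairing is supplied explicitly
by the caller (chain ids plus a (ts_residue, nts_residue, pam_index) map)
rather than inferred from hydrogen bonding: crosslinked complexes can contain
chemically modified or dual-conformation bases that defeat naive Watson-Crick
detection, so geometric validation (C1'-C1' distance within [8.5, 12.5] A) and
an explicit complementarity check guard against misregistration instead.

Alternate locations resolve to the highest-occupancy conformer (ties broken by
altloc identifier order); a specific conformer can be forced with ``altloc=``.
Coordinates are used in the file's frame with no symmetry expansion, and
residues are addressed by author numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import yaml

from .core import (
    Atom,
    BasePair,
    Duplex,
    Nucleotide,
    PairingError,
    ParseError,
    UsageError,
    ValidationError,
)

__all__ = [
    "C1_C1_RANGE",
    "StructureModel",
    "load_pairing_config",
    "read_structure",
    "select_duplex",
    "write_duplex_pdb",
]

#: Accepted C1'-C1' distance window for a Watson-Crick pair, Angstroms.
C1_C1_RANGE = (8.5, 12.5)

_RESNAME_TO_BASE = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
}
_BASE_TO_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}


@dataclass
class StructureModel:
    """Parsed structure: DNA nucleotides addressable by (chain, residue number).

    ``protein_residues`` keeps (chain_id, residue_number, name) tuples for any
    non-nucleic residues so callers can see what else the file contains.
    """

    path: str
    nucleotides: dict[tuple[str, int], Nucleotide] = field(default_factory=dict)
    protein_residues: list[tuple[str, int, str]] = field(default_factory=list)

    def nucleotide(self, chain_id: str, residue_number: int) -> Nucleotide:
        try:
            return self.nucleotides[(chain_id, residue_number)]
        except KeyError:
            raise PairingError(
                f"residue {chain_id}/{residue_number} not found in {self.path}"
            ) from None


def _is_nucleic(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_nucleic_acid():
        return True
    # Modified bases absent from the tables: recognize by the glycosidic C1'.
    return any(a.name == "C1'" for a in res)


def _resolve_altlocs(res: gemmi.Residue, altloc: str | None) -> list[gemmi.Atom]:
    """One atom per name: forced altloc if present, else highest occupancy."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    chosen = []
    for name, group in by_name.items():
        if altloc is not None:
            forced = [a for a in group if a.altloc == altloc]
            if forced:
                chosen.append(forced[0])
                continue
        chosen.append(min(group, key=lambda a: (-a.occ, a.altloc)))
    return chosen


def read_structure(
    path: str | Path, format: str = "auto", *, altloc: str | None = None
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is one of ``pdb``, ``mmcif`` or ``auto`` (detect from content).
    Only the first model of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise UsageError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    model = StructureModel(path=str(path))
    for chain in st[0]:
        for res in chain:
            num = res.seqid.num
            if _is_nucleic(res):
                atoms = [
                    Atom(a.name, [a.pos.x, a.pos.y, a.pos.z], a.element.name)
                    for a in _resolve_altlocs(res, altloc)
                ]
                nt = Nucleotide(
                    chain.name,
                    num,
                    _RESNAME_TO_BASE.get(res.name, res.name),
                    atoms,
                    icode=res.seqid.icode.strip(),
                )
                model.nucleotides.setdefault((chain.name, num), nt)
            else:
                model.protein_residues.append((chain.name, num, res.name))
    return model


def select_duplex(
    structure: StructureModel,
    ts_chain: str,
    nts_chain: str,
    pairing: Iterable[Sequence[int]],
    validate: bool = True,
    modified: Iterable[int] = (),
) -> Duplex:
    """Assemble a PAM-indexed duplex from an explicit pairing map.

    ``pairing`` holds (ts_residue_number, nts_residue_number, pam_index)
    triples; order is irrelevant. With ``validate`` on, each pair must pass the
    C1'-C1' distance window and Watson-Crick complementarity; pairs listed (by
    pam_index) in ``modified`` are exempt from the complementarity check.
    """
    modified = set(modified)
    pairs = []
    for ts_num, nts_num, pidx in pairing:
        ts = structure.nucleotide(ts_chain, ts_num)
        nts = structure.nucleotide(nts_chain, nts_num)
        pairs.append(BasePair(ts, nts, pidx))
    duplex = Duplex(pairs)
    if validate:
        problems = []
        lo, hi = C1_C1_RANGE
        for bp in duplex.pairs:
            d = bp.c1_c1_distance()
            if not lo <= d <= hi:
                problems.append(
                    f"pair {bp.pam_index:+d} ({bp.ts!r}:{bp.nts!r}): "
                    f"C1'-C1' distance {d:.2f} A outside [{lo}, {hi}]"
                )
            if bp.pam_index not in modified and not bp.is_watson_crick():
                problems.append(
                    f"pair {bp.pam_index:+d}: {bp.ts.base}:{bp.nts.base} is not "
                    "Watson-Crick complementary and not declared modified"
                )
        if problems:
            raise ValidationError("duplex validation failed:\n" + "\n".join(problems))
    return duplex


def load_pairing_config(path: str | Path) -> dict:
    """Load a pairing/junction config block from JSON or YAML.

    Expected keys: ts_chain, nts_chain, pairs (list of [ts_num, nts_num,
    pam_index]); optional: modified (list of pam_index), altloc.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, Mapping) or not {"ts_chain", "nts_chain", "pairs"} <= set(cfg):
        raise UsageError(
            f"{path}: config must define ts_chain, nts_chain and pairs"
        )
    return dict(cfg)


def write_duplex_pdb(duplex: Duplex, path: str | Path) -> None:
    """Write a duplex as a minimal standard PDB file (two chains)."""
    st = gemmi.Structure()
    st.name = "bendscan duplex"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}

    def add(nt: Nucleotide) -> None:
        chain = chains.get(nt.chain_id)
        if chain is None:
            chain = gemmi.Chain(nt.chain_id)
            chains[nt.chain_id] = chain
        res = gemmi.Residue()
        res.name = _BASE_TO_RESNAME.get(nt.base, nt.base)
        res.seqid = gemmi.SeqId(nt.residue_number, nt.icode or " ")
        for a in nt.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.position)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)

    for bp in duplex.pairs:
        add(bp.ts)
    # write the complementary strand in its own 5'->3' (ascending number) order
    for bp in sorted(duplex.pairs, key=lambda b: b.nts.residue_number):
        add(bp.nts)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
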