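import numpy as np
import pytest

from starc.ica import BinaryRankedArray

# the 18-element demonstration array: ranks of the seven distinguished
# elements (positions 1,3,4,6,7,14,18) are 4,1,6,3,2,7,5
WORKED_BINARY = "101101100000010001"
WORKED_RANKED = "401603200000070005"


@pytest.fixture
def worked_array() -> BinaryRankedArray:
    return BinaryRankedArray.from_rank_string(WORKED_RANKED)


def format_pdb_atom(serial, name, resname, chain, resseq, xyz, element=None,
                    occupancy=1.0, altloc=" "):
    x, y, z = xyz
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00          {element:>2s}"
    )


def make_pdb(residues, chain="A"):
    """residues: list of (resname, resseq, [(atom_name, (x,y,z)), ...])."""
    lines = []
    serial = 1
    for resname, resseq, atoms in residues:
        for name, xyz in atoms:
            elem = "H" if name.startswith(("H", "1H", "2H", "3H")) else name[0]
            lines.append(
                format_pdb_atom(serial, name, resname, chain, resseq, xyz,
                                element=elem)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_writer(tmp_path):
    def write(text, name="model.pdb"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
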