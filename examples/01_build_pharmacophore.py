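"""Build a structure-based pharmacophore from a receptor–ligand complex.

Generates a toy complex in which a polyol ligand donates four hydrogen bonds
to receptor side chains and accepts one, detects those bonds geometrically,
and assembles the feature model (F1–F4 donors, F5 acceptor).
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from pharmscreen import (
    build_model,
    detect_hbonds,
    galactose_like_spec,
    generate_complex,
    read_pdb_complex,
    save_model,
)

pdb_text, truth = generate_complex(galactose_like_spec(seed=1))
with TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "complex.pdb"
    pdb.write_text(pdb_text)
    cx = read_pdb_complex(pdb, "LIG")

contacts = detect_hbonds(cx)
print(f"{len(contacts)} hydrogen bonds detected (ground truth planted: {len(truth)})")
for c in contacts:
    print(f"  ligand atom {c.ligand_atom_index:2d} <-> {c.residue_label:8s}"
          f" {c.distance:.2f} A  {c.direction.value}")

model = build_model(contacts, cx)
save_model(model, "model.json")
print("\nPharmacophore model (saved to model.json):")
for f in model.features:
    print(f"  {f.label}: {f.kind.value:8s} at {f.position.round(2)} from {f.provenance}")
# Each feature marks a ligand heavy atom whose hydrogen bond the receptor
# must reproduce; donors outnumber acceptors 4:1, as for a bound sugar.
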