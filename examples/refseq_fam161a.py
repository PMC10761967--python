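"""Reproduce the FAM161A identity-ratio values from real RefSeq records.

This package never downloads from NCBI. To run this example (and the
corresponding acceptance test), manually fetch the FAM161A protein isoforms
for the four-species panel from the NCBI protein database — every annotated
isoform per species, so the longest-isoform selection is exercised; the
panel includes at least:

    human        NP_001188472 (716 aa, type 1) and other isoforms
    house mouse  XP_006514891 (700 aa, type 1), XP_006514893 (644 aa, type 2),
                 NP_001350211 (555 aa, testis type 3)
    bovine       the annotated FAM161A RefSeq isoforms
    rabbit       the annotated FAM161A RefSeq isoforms

Save them as plain-header FASTA at data/refseq/fam161a.fasta and write a
sidecar data/refseq/fam161a_metadata.tsv with columns
accession / gene_symbol / species, where species is one of
human, house_mouse, bovine, rabbit. Then run this script from the
repository root.

Because the original comparison tool's exact identity denominator is not
documented, the script reports both conventions (identical columns over all
alignment columns, and over the shorter sequence length).
"""

import sys
from pathlib import Path

from irscreen import (
    build_ortholog_group,
    extended_identity_ratio,
    identity_matrix,
    identity_ratio,
    protein_mass,
    read_fasta,
    read_metadata,
)

PANEL = ("human", "house_mouse", "bovine", "rabbit")
DATA = Path(__file__).resolve().parent.parent / "data" / "refseq"

fasta = DATA / "fam161a.fasta"
meta = DATA / "fam161a_metadata.tsv"
if not (fasta.exists() and meta.exists()):
    sys.exit(
        "RefSeq records not found under data/refseq/ — see this script's "
        "docstring for the manual download instructions."
    )

records = read_fasta(fasta, dialect="plain", metadata=read_metadata(meta))
group = build_ortholog_group(records, "FAM161A", PANEL)
for sp in PANEL:
    rec = group.members[sp]
    print(f"{sp:12s} longest isoform {rec.accession} ({len(rec)} aa)")

for denominator in ("alignment", "shorter"):
    m = identity_matrix(group, PANEL, denominator=denominator)
    ir = identity_ratio(m)  # pid(human, mouse) / pid(human, bovine)
    eir = extended_identity_ratio(m)  # mouse vs the human/bovine/rabbit trio
    print(f"denominator={denominator:9s}  IR {ir:.2f}  EIR {eir:.2f}")

type3 = next(
    (r for r in records if r.accession.startswith("NP_001350211")), None
)
if type3 is not None:
    print(f"type 3 isoform {type3.accession}: {len(type3)} aa, "
          f"predicted mass {protein_mass(type3.sequence):.0f} kDa")

# IR and EIR well below 1 say the house-mouse FAM161A diverged faster than
# its bovine/rabbit counterparts relative to human — the screen's hit.
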