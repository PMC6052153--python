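"""Download the published sequence data needed for the accession-based
reproduction into ``data/accessions/`` (requires network access).

Files produced:

- ``mitogenomes.gb`` — GenBank flat file with the three draft
  mitogenomes MH205752 (Spain Q1), MH205753 (Israel Q2), MH205754
  (Uganda "ASL") plus the reference mitogenomes JQ906700 (China Q1) and
  KY951447 (Burkina Faso Q1); annotated cox1 is extracted from these.
- ``panel_mitogenomes.gb`` — the remaining reference mitogenomes used
  for the conserved-site protein panel: KY951450, KY951448, KY951541,
  KX714967, KX714968, KJ778614, AY521259.

Run from the repository root:

    python scripts/fetch_accessions.py --email you@example.org

The published partial-haplotype sets (the GenBank entries assigned to
the Q1/Q2/Q3/Q5/ASL groups in the source literature) are curated lists
rather than single accessions; assemble them into per-group FASTA files
``q1.fasta`` ... ``asl.fasta`` in the same directory, with a
``group=`` key in each description line.
"""

import argparse
import sys
from pathlib import Path

CORE = ["MH205752", "MH205753", "MH205754", "JQ906700", "KY951447"]
PANEL = ["KY951450", "KY951448", "KY951541", "KX714967", "KX714968",
         "KJ778614", "AY521259"]

OUTDIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def fetch(accessions: list[str], email: str) -> str:
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(
        db="nucleotide", id=",".join(accessions), rettype="gb", retmode="text"
    ) as handle:
        return handle.read()


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--email", required=True, help="contact email for NCBI E-utilities")
    args = ap.parse_args()
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for name, accs in (("mitogenomes.gb", CORE), ("panel_mitogenomes.gb", PANEL)):
        dest = OUTDIR / name
        print(f"fetching {len(accs)} records -> {dest}")
        dest.write_text(fetch(accs, args.email))
    print("done; assemble the per-group haplotype FASTA files manually "
          "(see module docstring)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
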