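#!/usr/bin/env python
"""Predict the consequence of the CRISPR deletion allele.

Applies a 7 bp deletion to the demonstration coding sequence (or a user
CDS via --cds/--del-start/--del-len), translates the edited frame, and
reports frameshift / premature stop / predicted loss of function. Also
locates the sgRNA protospacer used for the real knockout as a site-search
demonstration.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from scnpair.knockout import classify_edit, find_oligo_sites, translate_cds
from scnpair.pipelines import _demo_cds
from scnpair.records import CodingRecord, read_coding_fasta

SGRNA = "GATGAGGTTCACCAGGTAGA"  # protospacer used for the scn1laa knockout

repo = Path(__file__).resolve().parent.parent
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cds", type=Path, default=None)
parser.add_argument("--del-start", type=int, default=None)
parser.add_argument("--del-len", type=int, default=7)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=repo / "results" / "genotype")
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

if args.cds is not None:
    cds = read_coding_fasta(args.cds)[0]
    if args.del_start is None:
        sys.exit("--cds requires --del-start")
    start, length = args.del_start, args.del_len
else:
    cds, start, length = _demo_cds(args.seed)

wt_prot, wt_stop = translate_cds(cds)
outcome = classify_edit(cds, start, length)
print(f"{cds.id}: {len(cds)} bp, wild-type protein {len(wt_prot)} aa "
      f"(stop codon {wt_stop})")
print(f"deletion of {length} bp at {start}: frameshift={outcome.frameshift}, "
      f"premature stop codon={outcome.premature_stop_codon_index}, "
      f"predicted loss of function={outcome.predicted_lof}")

report = {
    "cds_id": cds.id,
    "deletion_start": start,
    "deletion_length": length,
    "frameshift": outcome.frameshift,
    "premature_stop_codon_index": outcome.premature_stop_codon_index,
    "predicted_lof": outcome.predicted_lof,
}
(args.out_dir / "edit_outcome.json").write_text(json.dumps(report, indent=2))

# demonstrate strand-aware site search on a host carrying the guide
host = CodingRecord("host", cds.nucleotides[:30] + SGRNA + cds.nucleotides[30:])
hits = find_oligo_sites(host, SGRNA)
print(f"sgRNA {SGRNA}: {len(hits)} site(s) in the demonstration host at {hits}")
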