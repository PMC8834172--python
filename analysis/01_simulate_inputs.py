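#!/usr/bin/env python
"""Generate every input of the study with known ground truth.

Writes, under results/inputs/:
  family.fasta, domains.tsv, family_truth.tsv  — reference + two paralogs
    with two engineered differential-conservation hotspots (DII-S4, DIV-S1);
  lfp_wildtype.csv, lfp_mutant.csv, lfp_photic.csv (+ stimuli.txt, truth
    JSONs) — a quiet baseline, a recording with spontaneous events, and a
    5-min photic-stimulation recording (flashes every 30 s);
  cohort_null.csv, cohort_hyperactive.csv — 12 animals/group, 90 min in
    10-min bins; the hyperactive cohort has a 2.5x activity effect and ~15
    bursts/recording in group B.

Real inputs (Ensembl proteins via scripts/fetch_ensembl_sequences.py, or
exported tracking/electrode CSVs) can replace any of these downstream.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from scnpair.domains import write_domain_table
from scnpair.lfp import write_trace_csv
from scnpair.locomotor import write_cohort_csv
from scnpair.pipelines import _demo_family
from scnpair.records import write_fasta
from scnpair.synthetic import (
    CohortSimSpec,
    LfpSimSpec,
    family_truth_tables,
    simulate_cohort,
    simulate_lfp,
    write_stimulus_times,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path,
                    default=Path(__file__).resolve().parent.parent / "results" / "inputs")
args = parser.parse_args()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

truth = _demo_family(args.seed)
write_fasta([truth.reference, truth.paralog_a, truth.paralog_b], out / "family.fasta")
write_domain_table(list(truth.annotations), out / "domains.tsv")
family_truth_tables(truth).to_csv(out / "family_truth.tsv", sep="\t", index=False)
print(f"family: {len(truth.reference)}-residue reference, "
      f"{len(truth.annotations)} domains, truth-flagged: {sorted(truth.expected_flagged)}")

specs = {
    "wildtype": LfpSimSpec(duration_s=120, spont_event_rate_per_min=0.0, seed=args.seed),
    # same seed as wildtype: identical baseline noise, so the spectral
    # contrast between the two recordings isolates the injected events
    "mutant": LfpSimSpec(duration_s=120, spont_event_rate_per_min=6.0, seed=args.seed),
    "photic": LfpSimSpec(
        duration_s=300, spont_event_rate_per_min=1.0,
        stimulus_times=tuple(float(t) for t in np.arange(15.0, 300.0, 30.0)),
        stimulus_response_prob=1.0, seed=args.seed + 2,
    ),
}
for name, spec in specs.items():
    trace, lfp_truth = simulate_lfp(spec)
    write_trace_csv(trace, out / f"lfp_{name}.csv")
    (out / f"lfp_{name}_truth.json").write_text(json.dumps(lfp_truth, indent=2))
    print(f"lfp_{name}: {trace.duration_s:.0f} s, "
          f"{len(lfp_truth['all_onsets_s'])} injected events")
write_stimulus_times(specs["photic"].stimulus_times, out / "stimuli.txt")

for name, spec in {
    "null": CohortSimSpec(seed=args.seed),
    "hyperactive": CohortSimSpec(group_effect=2.5, burst_rate_a=0.2,
                                 burst_rate_b=15.0, seed=args.seed),
}.items():
    a, b, cohort_truth = simulate_cohort(spec)
    write_cohort_csv(a + b, out / f"cohort_{name}.csv")
    (out / f"cohort_{name}_truth.json").write_text(json.dumps(cohort_truth, indent=2))
    print(f"cohort_{name}: {len(a)}+{len(b)} animals, "
          f"{sum(cohort_truth['burst_counts'].values())} injected bursts")

print(f"inputs written to {out}")
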