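#!/usr/bin/env python
"""LFP phenotype: filtering, power spectra, spike detection, photosensitivity.

Reads the traces written by 01_simulate_inputs.py (or any time_s,value CSV),
runs the 50 Hz notch + 2.5-100 Hz band-pass, computes 40 s power spectra,
detects spikes against the robust-SD threshold, and assigns events to light
stimuli. Reports the wildtype/mutant contrast in event counts and band
power, and the stimulus-locked response fraction of the photic recording.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from scnpair.lfp import (
    detect_spikes,
    events_to_frame,
    power_spectrum,
    preprocess,
    read_trace_csv,
    stimulus_locked_responses,
)

repo = Path(__file__).resolve().parent.parent
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--inputs", type=Path, default=repo / "results" / "inputs")
parser.add_argument("--out-dir", type=Path, default=repo / "results" / "phenotype")
parser.add_argument("--spike-k", type=float, default=5.0)
args = parser.parse_args()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

summary = {}
for name in ("wildtype", "mutant", "photic"):
    stim_file = args.inputs / "stimuli.txt" if name == "photic" else None
    trace = read_trace_csv(args.inputs / f"lfp_{name}.csv", stimulus_path=stim_file)
    clean = preprocess(trace)
    spectrum = power_spectrum(clean, window_s=min(40.0, clean.duration_s))
    events = detect_spikes(clean, k=args.spike_k)
    table, fraction, events = stimulus_locked_responses(events, clean.stimulus_times)
    events_to_frame(events).to_csv(out / f"events_{name}.tsv", sep="\t", index=False)
    np.savetxt(out / f"spectrum_{name}.tsv",
               np.column_stack([spectrum.freqs, spectrum.power])[spectrum.freqs <= 120.0],
               delimiter="\t", header="freq_hz\tpower", comments="")
    summary[name] = {
        "n_events": len(events),
        "response_fraction": fraction,
        "low_band_power": spectrum.band_power(2.5, 20.0),
        "high_band_power": spectrum.band_power(40.0, 100.0),
    }
    frac = "n/a" if fraction is None else f"{fraction:.2f}"
    print(f"{name}: {len(events)} events, response fraction {frac}, band power "
          f"low {summary[name]['low_band_power']:.3g} / "
          f"high {summary[name]['high_band_power']:.3g}")

(out / "lfp_summary.json").write_text(json.dumps(summary, indent=2))
wt, mut = summary["wildtype"], summary["mutant"]
print(f"mutant vs wildtype: {mut['n_events']} vs {wt['n_events']} events; "
      f"band power elevated: low {mut['low_band_power'] > wt['low_band_power']}, "
      f"high {mut['high_band_power'] > wt['high_band_power']}")
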