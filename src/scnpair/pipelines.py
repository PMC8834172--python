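"""End-to-end pipeline drivers and configuration.

Two chains mirror the study design:

* genotype: (simulate or load) reference + two paralog proteins → affine-gap
  alignments → per-domain conservation report + flagged-domain summary, plus
  the knockout-allele consequence report on a coding sequence;
* phenotype: (simulate or load) LFP traces → preprocess → power spectra +
  spike detection + stimulus locking; locomotor cohorts → activity/burst
  metrics → exact Mann-Whitney group comparisons.

Every threshold defaults to the study's stated value (flag 20 percentage
points, burst cut-off 50 mm/s, alpha 0.01, spike threshold k=5, 40 s FFT
windows, 30 min habituation trim) and all randomness flows from one root
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import align as al
from . import domains as dm
from . import knockout as ko
from . import lfp as lf
from . import locomotor as lm
from . import synthetic as syn
from .records import CodingRecord, read_coding_fasta, read_protein_fasta, write_fasta

log = logging.getLogger("scnpair")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for the two pipelines.

    Path fields left as None are filled by the synthetic generators.
    """

    output_dir: str = "results"
    seed: int = 0

    # alignment / conservation
    ref_fasta: str | None = None
    paralog_a_fasta: str | None = None
    paralog_b_fasta: str | None = None
    domain_table: str | None = None
    gap_open: float = 10.0
    gap_extend: float = 1.0
    flag_threshold: float = 20.0

    # knockout allele
    cds_fasta: str | None = None
    del_start: int = 0  # 0 means "use the synthetic demonstration allele"
    del_len: int = 7

    # electrophysiology
    trace_csv: str | None = None
    stimuli_path: str | None = None
    trace_fs: float = 1000.0
    window_s: float = 40.0
    spike_k: float = 5.0
    trim_lead_s: float = 0.0  # set to 60 for real 13-min recordings

    # locomotor
    cohort_csv: str | None = None
    bin_minutes: float = 10.0
    trim_min: float = 30.0
    burst_cutoff_mm_s: float = 50.0
    alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _demo_family(seed: int) -> syn.FamilyTruth:
    """The default synthetic family: channel-like layout with two hotspots."""
    ref_length, layout = syn.channel_like_domain_layout(
        segment_length=40, linker_length=60, divergence_a=0.05, divergence_b=0.05
    )
    domains = []
    for d in layout:
        if d.label in {"DII-S4", "DIV-S1"}:  # differentially conserved hotspots
            d = dataclasses.replace(d, divergence_a=0.45, divergence_b=0.05)
        domains.append(d)
    spec = syn.ParalogFamilySpec(
        ref_length=ref_length, domains=tuple(domains), seed=seed
    )
    return syn.simulate_paralog_family(spec)


def _demo_cds(seed: int) -> tuple[CodingRecord, int, int]:
    """Synthetic demonstration CDS for the knockout report.

    Engineered so a 7 bp deletion at codon 9 shifts the frame into a TAA stop
    within a few codons — the same structural consequence as the real allele.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    safe = ["GCC", "GAC", "GAG", "TTC", "GGA", "CAC", "ATC", "AAG", "CTG"]
    for i in range(60):
        codons.append(safe[int(rng.integers(0, len(safe)))])
    codons.append("TAA")
    seq = "".join(codons)
    # deletion of 7 bp starting in codon 9 (position 25); the +1-shifted frame
    # is forced to read TAA shortly downstream by patching two codons
    seq = seq[:36] + "CTA" + "AGC" + seq[42:]
    return CodingRecord(id="synthetic_cds", nucleotides=seq), 25, 7


def run_genotype_pipeline(config: PipelineConfig) -> dict:
    """Alignment + domain conservation + allele consequence; writes reports.

    Returns a dict with the alignments, conservation records, protein-wide
    identities, flagged labels and the edit outcome.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = al.ScoringScheme.blosum62(config.gap_open, config.gap_extend)

    if config.ref_fasta and config.paralog_a_fasta and config.paralog_b_fasta:
        ref = read_protein_fasta(config.ref_fasta)[0]
        par_a = read_protein_fasta(config.paralog_a_fasta)[0]
        par_b = read_protein_fasta(config.paralog_b_fasta)[0]
        if not config.domain_table:
            raise FileNotFoundError("real sequences given but no domain table")
        domains = dm.read_domain_table(config.domain_table, ref_length=len(ref))
        truth = None
    else:
        truth = _demo_family(config.seed)
        ref, par_a, par_b = truth.reference, truth.paralog_a, truth.paralog_b
        domains = list(truth.annotations)
        write_fasta([ref, par_a, par_b], out / "family.fasta")
        dm.write_domain_table(domains, out / "domains.tsv")
        syn.family_truth_tables(truth).to_csv(
            out / "family_truth.tsv", sep="\t", index=False
        )

    log.info("aligning %s and %s against %s", par_a.id, par_b.id, ref.id)
    aln_a = al.global_align(ref, par_a, scheme)
    aln_b = al.global_align(ref, par_b, scheme)
    al.write_aligned_fasta(aln_a, out / "aligned_a.fasta")
    al.write_aligned_fasta(aln_b, out / "aligned_b.fasta")

    records = dm.score_domains(aln_a, aln_b, domains, config.flag_threshold)
    summary = dm.write_conservation_report(records, out / "conservation.tsv")
    pw_a = dm.proteinwide_identity(aln_a)
    pw_b = dm.proteinwide_identity(aln_b)
    flagged = [r.annotation.label for r in records if r.flagged]

    if config.cds_fasta:
        cds = read_coding_fasta(config.cds_fasta)[0]
        del_start, del_len = config.del_start, config.del_len
        if del_start < 1:
            raise ValueError("del_start must be a 1-based position for a real CDS")
    else:
        cds, del_start, del_len = _demo_cds(config.seed)
    outcome = ko.classify_edit(cds, del_start, del_len)
    edit_report = {
        "cds_id": cds.id,
        "deletion_start": outcome.deletion_start,
        "deletion_length": outcome.deletion_length,
        "frameshift": outcome.frameshift,
        "premature_stop_codon_index": outcome.premature_stop_codon_index,
        "predicted_lof": outcome.predicted_lof,
    }
    (out / "edit_outcome.json").write_text(json.dumps(edit_report, indent=2))

    summary_lines = [
        f"protein-wide identity: paralog A {pw_a:.1f}% (rounds to {round(pw_a)}), "
        f"paralog B {pw_b:.1f}% (rounds to {round(pw_b)})",
        summary,
        f"flagged domains: {', '.join(flagged) if flagged else 'none'}",
        f"allele: {del_len} bp deletion -> frameshift={outcome.frameshift}, "
        f"premature stop codon={outcome.premature_stop_codon_index}, "
        f"predicted LoF={outcome.predicted_lof}",
    ]
    (out / "genotype_summary.txt").write_text("\n".join(summary_lines) + "\n")
    return {
        "alignment_a": aln_a,
        "alignment_b": aln_b,
        "records": records,
        "proteinwide_identity_a": pw_a,
        "proteinwide_identity_b": pw_b,
        "flagged": flagged,
        "truth": truth,
        "edit_outcome": outcome,
        "summary": "\n".join(summary_lines),
    }


def _demo_lfp(seed: int) -> dict[str, tuple[lf.LfpTrace, dict]]:
    """Default synthetic recordings: a quiet wildtype-like baseline, a
    mutant-like trace with spontaneous events, and a photic-stimulation trace
    (light pulses every 30 s for 5 min)."""
    stims = tuple(float(t) for t in np.arange(15.0, 300.0, 30.0))
    return {
        "wildtype": syn.simulate_lfp(
            syn.LfpSimSpec(duration_s=120.0, spont_event_rate_per_min=0.0, seed=seed)
        ),
        # same seed as wildtype: identical baseline noise, events are the
        # only difference between the paired recordings
        "mutant": syn.simulate_lfp(
            syn.LfpSimSpec(duration_s=120.0, spont_event_rate_per_min=6.0, seed=seed)
        ),
        "photic": syn.simulate_lfp(
            syn.LfpSimSpec(
                duration_s=300.0,
                spont_event_rate_per_min=1.0,
                stimulus_times=stims,
                stimulus_response_prob=1.0,
                seed=seed + 2,
            )
        ),
    }


def run_phenotype_pipeline(config: PipelineConfig) -> dict:
    """LFP spectra/events plus locomotor comparisons; writes reports."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.trace_csv:
        traces = {
            "input": (
                lf.read_trace_csv(
                    config.trace_csv, fs=config.trace_fs,
                    stimulus_path=config.stimuli_path,
                ),
                None,
            )
        }
    else:
        traces = _demo_lfp(config.seed)

    lfp_results = {}
    for name, (trace, truth) in traces.items():
        clean = lf.preprocess(trace, trim_lead_s=config.trim_lead_s)
        spectrum = lf.power_spectrum(clean, window_s=min(config.window_s, clean.duration_s))
        events = lf.detect_spikes(clean, k=config.spike_k)
        table, fraction, events = lf.stimulus_locked_responses(
            events, clean.stimulus_times
        )
        lf.events_to_frame(events).to_csv(out / f"events_{name}.tsv", sep="\t", index=False)
        np.savetxt(
            out / f"spectrum_{name}.tsv",
            np.column_stack([spectrum.freqs, spectrum.power])[spectrum.freqs <= 120.0],
            delimiter="\t",
            header="freq_hz\tpower",
            comments="",
        )
        lfp_results[name] = {
            "n_events": len(events),
            "response_fraction": fraction,
            "low_band_power": spectrum.band_power(2.5, 20.0),
            "high_band_power": spectrum.band_power(40.0, 100.0),
            "truth": truth,
        }

    if config.cohort_csv:
        tracks = lm.read_cohort_csv(config.cohort_csv, bin_minutes=config.bin_minutes)
        groups = sorted({t.group for t in tracks})
        if len(groups) != 2:
            raise lm.TrackError(f"cohort CSV must contain exactly 2 groups, got {groups}")
        cohort_a = [t for t in tracks if t.group == groups[0]]
        cohort_b = [t for t in tracks if t.group == groups[1]]
        cohort_truth = None
    else:
        cohort_a, cohort_b, cohort_truth = syn.simulate_cohort(
            syn.CohortSimSpec(seed=config.seed)
        )
        lm.write_cohort_csv(cohort_a + cohort_b, out / "cohort.csv")

    loco_results = {}
    for metric in ("activity_total", "burst_count"):
        comparison, table = lm.compare_groups(
            cohort_a,
            cohort_b,
            metric=metric,
            trim_min=config.trim_min,
            cutoff_mm_s=config.burst_cutoff_mm_s,
            alpha=config.alpha,
        )
        table.to_csv(out / f"locomotor_{metric}.tsv", sep="\t", index=False)
        loco_results[metric] = {
            "U": comparison.statistic_U,
            "p_two_sided": comparison.p_two_sided,
            "significant": comparison.significant,
            "method": comparison.method,
        }

    summary_lines = ["LFP:"]
    for name, res in lfp_results.items():
        frac = "n/a" if res["response_fraction"] is None else f"{res['response_fraction']:.2f}"
        summary_lines.append(
            f"  {name}: {res['n_events']} events, response fraction {frac}, "
            f"band power low {res['low_band_power']:.3g} / high {res['high_band_power']:.3g}"
        )
    summary_lines.append("locomotor (Mann-Whitney, two-sided):")
    for metric, res in loco_results.items():
        verdict = "significant" if res["significant"] else "n.s."
        summary_lines.append(
            f"  {metric}: U={res['U']:.1f}, p={res['p_two_sided']:.4g} ({verdict} at "
            f"alpha={config.alpha})"
        )
    (out / "phenotype_summary.txt").write_text("\n".join(summary_lines) + "\n")
    json_safe = {
        "lfp": {
            k: {kk: vv for kk, vv in v.items() if kk != "truth"}
            for k, v in lfp_results.items()
        },
        "locomotor": loco_results,
    }
    (out / "phenotype_results.json").write_text(json.dumps(json_safe, indent=2))
    return {"lfp": lfp_results, "locomotor": loco_results,
            "cohort_truth": cohort_truth, "summary": "\n".join(summary_lines)}
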