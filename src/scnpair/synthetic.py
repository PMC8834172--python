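"""Synthetic inputs with known ground truth for every pipeline stage.

Stands in for the three kinds of real-world input — Ensembl protein/CDS
sequences, electrode LFP recordings, and tracking-chamber locomotor exports —
so the full genotype-to-phenotype analysis can run and be validated offline.

Three generators:

* :func:`simulate_paralog_family` — a reference protein with a channel-like
  domain architecture and two paralogs diverged site-wise at controlled
  per-domain rates. Substitutions replace a residue by a uniformly chosen
  *different* residue, so expected per-domain identity is exactly ``1 - d``.
* :func:`simulate_lfp` — baseline noise (white or 1/f) with optional 50 Hz
  mains contamination, spontaneous biphasic events at Poisson times, and
  stimulus-locked events after light stimuli; all injected onsets recorded.
* :func:`simulate_cohort` — two locomotor groups (default n=12/group, 90 min
  in 10-min bins) with configurable hyperactivity (multiplicative distance
  effect) and burst-movement rates; per-bin distances are zero-truncated
  Gaussian, bursts are velocity excursions above the 50 mm/s cut-off.

Determinism: every generator consumes a single integer seed through
``numpy.random.SeedSequence`` children, so identical specs reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import DomainAnnotation, SHORT_PEPTIDE_LENGTH, _validate_table
from .lfp import LfpTrace
from .locomotor import BURST_CUTOFF_MM_S, LocomotorTrack
from .records import AMINO_ACIDS, ProteinRecord


class SpecError(ValueError):
    """Raised for invalid simulation specifications."""


# ---------------------------------------------------------------------------
# paralog family


@dataclass(frozen=True)
class DomainDivergenceSpec:
    """One annotated span with its per-site substitution probabilities."""

    label: str
    klass: str
    start: int
    end: int
    divergence_a: float
    divergence_b: float
    channel_domain: str | None = None

    def __post_init__(self) -> None:
        for name in ("divergence_a", "divergence_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"domain {self.label!r}: {name}={v} outside [0,1]")


@dataclass(frozen=True)
class ParalogFamilySpec:
    """Parameters for one simulated reference + two-paralog family."""

    ref_length: int
    domains: tuple[DomainDivergenceSpec, ...]
    inter_domain_divergence: float = 0.05
    indel_rate: float = 0.0
    flag_threshold: float = 0.20  # on |divergence_a - divergence_b|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_length < 1:
            raise SpecError("ref_length must be positive")
        if not 0.0 <= self.inter_domain_divergence <= 1.0:
            raise SpecError("inter_domain_divergence outside [0,1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise SpecError("indel_rate outside [0,1]")
        anns = [
            DomainAnnotation(
                label=d.label,
                klass=d.klass,
                start=d.start,
                end=d.end,
                channel_domain=d.channel_domain,
            )
            for d in self.domains
        ]
        _validate_table(anns, self.ref_length)  # overlap / bounds / dup labels


@dataclass(frozen=True)
class FamilyTruth:
    """A simulated family plus its ground truth."""

    reference: ProteinRecord
    paralog_a: ProteinRecord
    paralog_b: ProteinRecord
    annotations: tuple[DomainAnnotation, ...]
    expected_flagged: frozenset[str]
    realized_identity_a: dict[str, float]  # site-level % identity per domain
    realized_identity_b: dict[str, float]

    def __post_init__(self) -> None:
        labels = {a.label for a in self.annotations}
        if not set(self.expected_flagged) <= labels:
            raise SpecError("expected_flagged contains unknown domain labels")


def _mutate(residue_idx: np.ndarray, d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Site-wise substitution: with prob d, replace by a different residue (uniform)."""
    hit = rng.random(residue_idx.size) < d
    offsets = rng.integers(1, len(AMINO_ACIDS), size=residue_idx.size)
    out = residue_idx.copy()
    out[hit] = (residue_idx[hit] + offsets[hit]) % len(AMINO_ACIDS)
    return out


def simulate_paralog_family(spec: ParalogFamilySpec) -> FamilyTruth:
    """Draw a reference and two site-wise diverged paralogs with known truth.

    The reference is uniform over the 20 canonical residues. Each paralog is
    derived independently: inside a domain span sites mutate with that
    domain's divergence, elsewhere with ``inter_domain_divergence``. Truth
    flags domains where |divergence_a - divergence_b| exceeds the flag
    threshold (strictly). Optional 1-3 residue indels are placed only outside
    annotated domains so per-domain truth stays well-defined.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_ref, rng_a, rng_b, rng_indel = (np.random.default_rng(c) for c in ss.spawn(4))

    L = spec.ref_length
    ref_idx = rng_ref.integers(0, len(AMINO_ACIDS), size=L)

    d_a = np.full(L, spec.inter_domain_divergence)
    d_b = np.full(L, spec.inter_domain_divergence)
    in_domain = np.zeros(L, dtype=bool)
    for dom in spec.domains:
        sl = slice(dom.start - 1, dom.end)
        d_a[sl] = dom.divergence_a
        d_b[sl] = dom.divergence_b
        in_domain[sl] = True

    a_idx = _mutate(ref_idx, d_a, rng_a)
    b_idx = _mutate(ref_idx, d_b, rng_b)

    realized_a, realized_b = {}, {}
    for dom in spec.domains:
        sl = slice(dom.start - 1, dom.end)
        realized_a[dom.label] = 100.0 * float(np.mean(a_idx[sl] == ref_idx[sl]))
        realized_b[dom.label] = 100.0 * float(np.mean(b_idx[sl] == ref_idx[sl]))

    def to_str(idx: np.ndarray, rng: np.random.Generator | None) -> str:
        chars = [AMINO_ACIDS[i] for i in idx]
        if spec.indel_rate > 0 and rng is not None:
            out: list[str] = []
            for pos, ch in enumerate(chars):
                if not in_domain[pos] and rng.random() < spec.indel_rate:
                    if rng.random() < 0.5:  # deletion of 1-3 sites handled as 1 here
                        continue
                    ins_len = int(rng.integers(1, 4))
                    ins = "".join(
                        AMINO_ACIDS[i]
                        for i in rng.integers(0, len(AMINO_ACIDS), size=ins_len)
                    )
                    out.append(ins + ch)
                else:
                    out.append(ch)
            return "".join(out)
        return "".join(chars)

    reference = ProteinRecord(id="REF", residues="".join(AMINO_ACIDS[i] for i in ref_idx))
    paralog_a = ProteinRecord(id="PARALOG_A", residues=to_str(a_idx, rng_indel))
    paralog_b = ProteinRecord(id="PARALOG_B", residues=to_str(b_idx, rng_indel))

    annotations = tuple(
        DomainAnnotation(
            label=d.label,
            klass=d.klass,
            start=d.start,
            end=d.end,
            channel_domain=d.channel_domain,
            short_peptide=(d.end - d.start + 1) < SHORT_PEPTIDE_LENGTH,
        )
        for d in spec.domains
    )
    flagged = frozenset(
        d.label
        for d in spec.domains
        if abs(d.divergence_a - d.divergence_b) > spec.flag_threshold
    )
    return FamilyTruth(
        reference=reference,
        paralog_a=paralog_a,
        paralog_b=paralog_b,
        annotations=annotations,
        expected_flagged=flagged,
        realized_identity_a=realized_a,
        realized_identity_b=realized_b,
    )


def channel_like_domain_layout(
    n_channel_domains: int = 4,
    segment_length: int = 30,
    linker_length: int = 40,
    divergence_a: float = 0.05,
    divergence_b: float = 0.05,
) -> tuple[int, tuple[DomainDivergenceSpec, ...]]:
    """A compact sodium-channel-like architecture: 4 homologous domains x S1-S6.

    Returns (ref_length, domain specs). Divergences are uniform here; callers
    override individual domains to create differential-conservation hotspots.
    """
    roman = ["I", "II", "III", "IV"][:n_channel_domains]
    specs: list[DomainDivergenceSpec] = []
    pos = 1 + linker_length  # N-terminus before the first domain
    specs.append(
        DomainDivergenceSpec(
            label="N-term", klass="N_terminus", start=1, end=linker_length,
            divergence_a=divergence_a, divergence_b=divergence_b,
        )
    )
    for dom in roman:
        for seg in range(1, 7):
            specs.append(
                DomainDivergenceSpec(
                    label=f"D{dom}-S{seg}",
                    klass="TM_segment",
                    start=pos,
                    end=pos + segment_length - 1,
                    divergence_a=divergence_a,
                    divergence_b=divergence_b,
                    channel_domain=dom,
                )
            )
            pos += segment_length + 5  # short inter-segment loops stay unannotated
        pos += linker_length  # cytoplasmic linker between homologous domains
    ref_length = pos + linker_length
    return ref_length, tuple(specs)


def recovery_family_spec(
    seed: int,
    n_domains: int = 6,
    domain_length: int = 150,
    linker_length: int = 20,
    n_flagged: int = 2,
    d_high: float = 0.45,
    d_low: float = 0.05,
) -> ParalogFamilySpec:
    """A compact family spec for flag-recovery studies.

    ``n_domains`` equal-length domains separated by unannotated linkers; the
    first ``n_flagged`` domains get strongly asymmetric divergence
    (``d_high`` vs ``d_low`` in paralog A vs B), the rest are symmetric at
    ``d_low``.
    """
    domains = []
    pos = 1 + linker_length
    for i in range(n_domains):
        da = d_high if i < n_flagged else d_low
        domains.append(
            DomainDivergenceSpec(
                label=f"dom{i + 1}",
                klass="other",
                start=pos,
                end=pos + domain_length - 1,
                divergence_a=da,
                divergence_b=d_low,
            )
        )
        pos += domain_length + linker_length
    return ParalogFamilySpec(
        ref_length=pos + linker_length,
        domains=tuple(domains),
        inter_domain_divergence=d_low,
        seed=seed,
    )


def family_truth_tables(truth: FamilyTruth) -> pd.DataFrame:
    """Tabular truth (per-domain realized identities and flags) for TSV export."""
    rows = []
    for ann in truth.annotations:
        rows.append(
            {
                "label": ann.label,
                "class": ann.klass,
                "channel_domain": ann.channel_domain or "",
                "start": ann.start,
                "end": ann.end,
                "realized_identity_a": truth.realized_identity_a[ann.label],
                "realized_identity_b": truth.realized_identity_b[ann.label],
                "expected_flagged": ann.label in truth.expected_flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LFP


@dataclass(frozen=True)
class LfpSimSpec:
    """Parameters for one simulated LFP recording (defaults: 1000 Hz sampling)."""

    duration_s: float = 120.0
    fs: float = 1000.0
    noise_model: str = "white"  # "white" or "one_over_f"
    noise_amplitude: float = 1.0  # SD of the baseline noise
    spont_event_rate_per_min: float = 6.0
    event_amplitude: float = 10.0  # peak, in units of noise SD
    event_lobe_width_s: float = 0.030  # each half of the biphasic template
    stimulus_times: tuple[float, ...] = ()
    stimulus_response_prob: float = 1.0
    response_window_s: float = 0.5
    mains_hum_amplitude: float = 0.0  # 50 Hz contaminant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SpecError(f"sampling rate must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise SpecError("duration must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise SpecError("duration_s x fs must be an integer sample count")
        if self.noise_model not in {"white", "one_over_f"}:
            raise SpecError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.stimulus_response_prob <= 1.0:
            raise SpecError("stimulus_response_prob outside [0,1]")
        for t in self.stimulus_times:
            if not 0.0 <= t <= self.duration_s:
                raise SpecError(f"stimulus time {t} outside [0, {self.duration_s}]")


def biphasic_template(fs: float, lobe_width_s: float, amplitude: float) -> np.ndarray:
    """One positive then one negative half-sine lobe."""
    n_lobe = max(1, int(round(lobe_width_s * fs)))
    lobe = np.sin(np.pi * np.arange(n_lobe) / n_lobe)
    return amplitude * np.concatenate([lobe, -lobe])


def simulate_lfp(spec: LfpSimSpec) -> tuple[LfpTrace, dict]:
    """Simulate one LFP trace; returns the trace and its injected-event truth.

    Truth dict keys: ``spontaneous_onsets_s``, ``locked_onsets_s`` (parallel
    to the subset of stimuli that responded), ``responding_stimuli`` (indices),
    ``all_onsets_s`` (sorted union).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_events = (np.random.default_rng(c) for c in ss.spawn(2))
    n = int(round(spec.duration_s * spec.fs))

    if spec.noise_amplitude > 0:
        if spec.noise_model == "white":
            x = rng_noise.normal(0.0, spec.noise_amplitude, size=n)
        else:
            white = rng_noise.normal(0.0, 1.0, size=n)
            spec_f = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
            shaping = np.ones_like(f)
            shaping[1:] = 1.0 / np.sqrt(f[1:])
            shaping[0] = 0.0
            x = np.fft.irfft(spec_f * shaping, n=n)
            x *= spec.noise_amplitude / max(np.std(x), 1e-12)
    else:
        x = np.zeros(n)

    if spec.mains_hum_amplitude > 0:
        t = np.arange(n) / spec.fs
        x = x + spec.mains_hum_amplitude * np.sin(2 * np.pi * 50.0 * t)

    template = biphasic_template(
        spec.fs, spec.event_lobe_width_s, spec.event_amplitude * spec.noise_amplitude
        if spec.noise_amplitude > 0
        else spec.event_amplitude
    )
    tmpl_s = template.size / spec.fs

    # spontaneous events: homogeneous Poisson over the usable span
    usable = spec.duration_s - tmpl_s
    n_spont = (
        rng_events.poisson(spec.spont_event_rate_per_min * spec.duration_s / 60.0)
        if usable > 0 and spec.spont_event_rate_per_min > 0
        else 0
    )
    spont = np.sort(rng_events.uniform(0.0, usable, size=n_spont)) if n_spont else np.array([])

    locked = []
    responding = []
    for si, stim in enumerate(spec.stimulus_times):
        if rng_events.random() < spec.stimulus_response_prob:
            latency = rng_events.uniform(0.02, max(0.04, spec.response_window_s - tmpl_s))
            onset = min(stim + latency, spec.duration_s - tmpl_s)
            locked.append(onset)
            responding.append(si)

    for onset in list(spont) + locked:
        i0 = int(round(onset * spec.fs))
        x[i0 : i0 + template.size] += template[: max(0, n - i0)]

    trace = LfpTrace(
        fs=spec.fs,
        samples=x,
        stimulus_times=tuple(spec.stimulus_times),
        meta={"synthetic": True, "seed": spec.seed},
    )
    truth = {
        "spontaneous_onsets_s": [float(t) for t in spont],
        "locked_onsets_s": [float(t) for t in locked],
        "responding_stimuli": responding,
        "all_onsets_s": sorted([float(t) for t in spont] + [float(t) for t in locked]),
    }
    return trace, truth


# ---------------------------------------------------------------------------
# locomotor cohorts


@dataclass(frozen=True)
class CohortSimSpec:
    """Two-group locomotor simulation (defaults: the standard 90-min assay)."""

    n_per_group: int = 12
    duration_min: float = 90.0
    bin_min: float = 10.0
    baseline_distance_mm: float = 1200.0  # mean distance per bin, group A
    distance_cv: float = 0.20  # per-bin coefficient of variation
    group_effect: float = 1.0  # multiplicative activity factor, group B
    burst_rate_a: float = 0.0  # expected bursts per recording, group A
    burst_rate_b: float = 0.0
    burst_velocity_mm_s: float = 20.0  # excursion magnitude above the cut-off
    baseline_velocity_mm_s: float = 25.0  # typical sub-cut-off bin peak velocity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SpecError("need at least 2 animals per group")
        n_bins = self.duration_min / self.bin_min
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise SpecError("duration_min must be divisible by bin_min")
        if self.group_effect <= 0:
            raise SpecError("group_effect must be positive")
        if min(self.burst_rate_a, self.burst_rate_b) < 0:
            raise SpecError("burst rates must be non-negative")


def _simulate_track(
    animal_id: str,
    group: str,
    spec: CohortSimSpec,
    effect: float,
    burst_rate: float,
    rng: np.random.Generator,
) -> tuple[LocomotorTrack, int]:
    n_bins = int(round(spec.duration_min / spec.bin_min))
    mean = spec.baseline_distance_mm * effect
    dist = rng.normal(mean, spec.distance_cv * mean, size=n_bins)
    dist = np.clip(dist, 0.0, None)  # zero-truncated activity
    vel = np.clip(
        rng.normal(spec.baseline_velocity_mm_s, 8.0, size=n_bins),
        0.0,
        BURST_CUTOFF_MM_S - 5.0,
    )
    k = int(rng.poisson(burst_rate))
    # place bursts in non-adjacent bins so each is one supra-threshold run
    placed: list[int] = []
    for b in rng.permutation(n_bins):
        if len(placed) == k:
            break
        if all(abs(b - p) > 1 for p in placed):
            placed.append(int(b))
    for b in placed:
        vel[b] = BURST_CUTOFF_MM_S + spec.burst_velocity_mm_s + rng.uniform(0.0, 5.0)
    track = LocomotorTrack(
        animal_id=animal_id,
        group=group,
        bins=tuple((i, float(dist[i]), float(vel[i])) for i in range(n_bins)),
        bin_minutes=spec.bin_min,
    )
    return track, len(placed)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[list[LocomotorTrack], list[LocomotorTrack], dict]:
    """Simulate groups A and B; returns (tracks_a, tracks_b, truth).

    Truth holds the injected burst count per animal (``burst_counts``); a
    burst occupies one bin and distinct bursts occupy non-adjacent bins, so
    run-based burst counting recovers the truth exactly on noiseless calls.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 * spec.n_per_group)
    tracks_a, tracks_b = [], []
    burst_counts: dict[str, int] = {}
    for i in range(spec.n_per_group):
        t, k = _simulate_track(
            f"A{i + 1:02d}", "A", spec, 1.0, spec.burst_rate_a,
            np.random.default_rng(children[i]),
        )
        tracks_a.append(t)
        burst_counts[t.animal_id] = k
    for i in range(spec.n_per_group):
        t, k = _simulate_track(
            f"B{i + 1:02d}", "B", spec, spec.group_effect, spec.burst_rate_b,
            np.random.default_rng(children[spec.n_per_group + i]),
        )
        tracks_b.append(t)
        burst_counts[t.animal_id] = k
    truth = {"burst_counts": burst_counts}
    return tracks_a, tracks_b, truth


def write_stimulus_times(times: list[float] | tuple[float, ...], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in times:
            fh.write(f"{t:.6f}\n")
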