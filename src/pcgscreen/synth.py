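"""Seeded synthetic phonocardiogram cohort generator.

Emulates the statistical structure the screening analysis assumes: four
auscultation positions per participant (aortic, pulmonic, tricuspid,
mitral), S1/S2/murmur waveform structure, murmur loudness tied to valvular
disease severity, the aortic-gradient (AVPGmean) to stenosis-grade cutoff
logic (15/20/40 mm Hg), position-specific noise-flag prevalences, two noisy
annotators, and clinical covariates with disease associations and
missingness. The generator is the test bed for every downstream stage; it
makes no claim of hemodynamic realism.

Murmur loudness convention: grade ``g`` maps to a murmur/S1 RMS ratio of
``0.12 * g``, putting grade 1 near the audibility floor and grades 5-6 at
murmur-dominant loudness, consistent with a scale where grades above 3
reflect loudness only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

POSITIONS = {1: "aortic", 2: "pulmonic", 3: "tricuspid", 4: "mitral"}

#: AVPGmean cutoffs (mm Hg) for mild / moderate / severe aortic stenosis.
AS_CUTOFFS_MMHG = (15.0, 20.0, 40.0)

#: murmur/S1 RMS ratio per murmur-grade unit
GRADE_RMS_SLOPE = 0.12

S1_DURATION_S = 0.12
S2_DURATION_S = 0.09


def as_grade_from_avpg(avpg_mean_mmhg: float) -> int:
    """Deterministic stenosis grade from the mean aortic pressure gradient."""
    g = 0
    for cut in AS_CUTOFFS_MMHG:
        if avpg_mean_mmhg >= cut:
            g += 1
    return g


@dataclass
class CohortConfig:
    n_participants: int
    sample_rate_hz: int = 2205
    duration_s: float = 10.0
    seed: int = 0
    # disease prevalences (cohort fractions)
    p_as: float = 0.021          # AS >= 1, i.e. AVPGmean >= 15 mm Hg
    p_ms: float = 0.006          # MS >= 1
    p_ar3: float = 0.071         # AR >= 3
    p_mr3: float = 0.137         # MR >= 3
    noise_flag_probs: tuple[float, float, float, float] = (0.061, 0.053, 0.028, 0.071)
    annotator_noise_sd: float = 0.5
    p_innocent_murmur: float = 0.16
    # clinical covariate effects (directional; magnitudes are generator knobs)
    age_shift_vhd_y: float = 7.0
    heart_rate_shift_vhd_bpm: float = -3.0
    missingness: dict = field(default_factory=lambda: {
        "breathless_rest": 0.0424,
        "breathless_level": 0.0424,
        "breathless_uphill": 0.0424,
        "mmrc": 0.0603,
        "heart_rate": 0.0612,
    })

    def __post_init__(self):
        probs = [self.p_as, self.p_ms, self.p_ar3, self.p_mr3,
                 self.p_innocent_murmur, *self.noise_flag_probs,
                 *self.missingness.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sample_rate_hz <= 400:
            raise ValueError("sample_rate_hz must exceed 400")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.annotator_noise_sd < 0:
            raise ValueError("annotator_noise_sd must be >= 0")


@dataclass
class PcgRecording:
    """One auscultation position's audio plus its annotations."""

    participant_id: str
    position: int
    samples: np.ndarray
    sample_rate_hz: int
    annotator_grades: tuple[int, int]
    noise_flags: tuple[bool, bool]

    @property
    def murmur_grade(self) -> float:
        """Label convention: the mean of the two annotators' grades."""
        return 0.5 * (self.annotator_grades[0] + self.annotator_grades[1])

    @property
    def is_noisy(self) -> bool:
        """Noisy unless both annotators agreed the recording is clean."""
        return bool(self.noise_flags[0] or self.noise_flags[1])


@dataclass
class ParticipantRecord:
    participant_id: str
    recordings: list
    as_grade: int
    ms_grade: int
    ar_grade: int
    mr_grade: int
    avpg_mean: float
    clinical: dict

    @property
    def all_noisy(self) -> bool:
        return all(r.is_noisy for r in self.recordings)


@dataclass
class GroundTruth:
    """Per-participant and per-recording latent state, for oracle tests."""

    true_grades: dict          # pid -> 4-vector of true murmur grades
    avpg: dict                 # pid -> AVPGmean (mm Hg)
    as_grade: dict
    ms_grade: dict
    ar_grade: dict
    mr_grade: dict
    heart_rate_bpm: dict
    s1_onsets: dict            # (pid, position) -> sample indices of S1 onsets
    states: dict               # (pid, position) -> per-sample state codes 0..3


def _bandpass_noise(rng, n, fs, lo, hi):
    noise = rng.standard_normal(n)
    ny = fs / 2.0
    hi = min(hi, 0.95 * ny)
    sos = signal.butter(2, [lo / ny, hi / ny], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, noise)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0


def synthesize_pcg(heart_rate_bpm: float, murmur_grade_systolic: float,
                   murmur_grade_diastolic: float, sample_rate_hz: int,
                   duration_s: float, seed,
                   noisy: bool = False, spikes: int = 0):
    """Render one synthetic phonocardiogram.

    S1 and S2 are amplitude-windowed band-limited noise bursts (120 ms and
    90 ms, 40-200 Hz); the systolic interval follows a linear function of
    cycle length; murmurs are band-passed noise whose RMS relative to S1
    follows the linear grade-loudness mapping. Returns ``(waveform,
    s1_onsets, state_labels)`` where onsets mark complete cycles only and
    state labels code S1=0, systole=1, S2=2, diastole=3 per sample.
    """
    if not 30 <= heart_rate_bpm <= 150:
        raise ValueError("heart_rate_bpm must lie in [30, 150]")
    if murmur_grade_systolic < 0 or murmur_grade_diastolic < 0:
        raise ValueError("murmur grades must be >= 0")
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    states = np.full(n, 3, dtype=np.uint8)  # lead-in/out counted as diastole

    cycle_s = 60.0 / heart_rate_bpm
    sys_s = (130.0 + 0.22 * cycle_s * 1000.0) / 1000.0  # S1 onset -> S2 onset
    t0 = 0.02 + rng.uniform(0.0, 0.06)

    # cycle onsets with mild physiological jitter
    onsets_s = []
    t = t0
    while t + cycle_s <= duration_s:
        onsets_s.append(t)
        t += cycle_s * (1.0 + 0.015 * rng.standard_normal())
    s1_onsets = np.array([int(round(o * fs)) for o in onsets_s], dtype=int)

    n_s1 = int(round(S1_DURATION_S * fs))
    n_s2 = int(round(S2_DURATION_S * fs))
    a_s1 = 0.40
    s1_rms_ref = None

    for o in s1_onsets:
        # S1 burst
        e = min(o + n_s1, n)
        burst = _bandpass_noise(rng, n_s1, fs, 40, 150) * np.hanning(n_s1)
        if _rms(burst) > 0:
            burst *= a_s1 / (3.0 * _rms(burst))  # peak ~ a_s1
        x[o:e] += burst[: e - o]
        states[o:e] = 0
        if s1_rms_ref is None:
            s1_rms_ref = _rms(burst)
        # systole
        sys_end = min(o + int(round(sys_s * fs)), n)
        states[o + n_s1:sys_end] = 1
        # S2 burst
        e2 = min(sys_end + n_s2, n)
        burst2 = _bandpass_noise(rng, n_s2, fs, 50, 200) * np.hanning(n_s2)
        if _rms(burst2) > 0:
            burst2 *= 0.7 * a_s1 / (3.0 * _rms(burst2))
        x[sys_end:e2] += burst2[: e2 - sys_end]
        states[sys_end:e2] = 2
        # diastole runs until the next S1 (already state 3)

    if s1_rms_ref is None:
        s1_rms_ref = a_s1 / 3.0

    # murmurs: band-passed noise shaped inside the systolic/diastolic windows
    if murmur_grade_systolic > 0 and len(s1_onsets):
        mur = _bandpass_noise(rng, n, fs, 100, 440)
        env = np.zeros(n)
        for o in s1_onsets:
            a = o + n_s1
            b = min(o + int(round(sys_s * fs)), n)
            if b > a:
                env[a:b] = np.sin(np.linspace(0, np.pi, b - a))  # diamond shape
        mur *= env
        r = _rms(mur[env > 0])
        if r > 0:
            mur *= GRADE_RMS_SLOPE * murmur_grade_systolic * s1_rms_ref / r
            x += mur
    if murmur_grade_diastolic > 0 and len(s1_onsets):
        mur = _bandpass_noise(rng, n, fs, 150, 400)
        env = np.zeros(n)
        for i, o in enumerate(s1_onsets):
            a = o + int(round(sys_s * fs)) + n_s2
            b = s1_onsets[i + 1] if i + 1 < len(s1_onsets) else min(o + int(round(cycle_s * fs)), n)
            b -= int(0.02 * fs)
            if b > a:
                env[a:b] = np.linspace(1.0, 0.3, b - a)  # decrescendo
        mur *= env
        r = _rms(mur[env > 0])
        if r > 0:
            mur *= GRADE_RMS_SLOPE * murmur_grade_diastolic * s1_rms_ref / r
            x += mur

    # ambient noise floor
    x += 0.03 * s1_rms_ref * rng.standard_normal(n)
    if noisy:
        # low-SNR broadband interference so "noisy" is physically meaningful
        x += 2.0 * s1_rms_ref * _bandpass_noise(rng, n, fs, 20, min(1000, fs * 0.45))
    for _ in range(spikes):
        p = rng.integers(0, n)
        width = max(3, int(0.004 * fs))
        x[p:p + width] += 10.0 * a_s1 * np.hanning(min(width, n - p))

    peak = np.max(np.abs(x)) if n else 0.0
    if peak > 0.95:
        x *= 0.95 / peak
    return x, s1_onsets, states


def _draw_avpg(rng, is_as: bool) -> float:
    if is_as:
        return float(min(15.0 + rng.exponential(12.0), 75.0))
    return float(np.clip(rng.lognormal(np.log(5.0), 0.35), 2.0, 14.5))


def _true_position_grades(rng, avpg, as_g, ms_g, ar_g, mr_g, innocent: bool):
    """Map disease state to continuous murmur grades per position.

    Returns (systolic grades, diastolic grades), 4-vectors ordered
    aortic/pulmonic/tricuspid/mitral. The aortic-stenosis component is a
    monotone function of the pressure gradient, loudest at the aortic and
    pulmonic positions.
    """
    sys_g = np.zeros(4)
    dia_g = np.zeros(4)
    if as_g >= 1:
        g = np.clip(1.0 + 2.2 * np.log2(avpg / 15.0), 0.0, 6.0)
        sys_g = np.maximum(sys_g, g * np.array([1.0, 0.9, 0.55, 0.35]))
    elif avpg > 10.0:
        # slightly elevated gradients produce faint aortic flow murmurs
        g = 0.4 * (avpg - 10.0) / 5.0
        sys_g = np.maximum(sys_g, g * np.array([1.0, 0.9, 0.3, 0.2]))
    if mr_g >= 2:
        g = 0.7 * (mr_g - 1.5)
        sys_g = np.maximum(sys_g, g * np.array([0.2, 0.25, 0.35, 1.0]))
    if innocent:
        # innocent flow murmurs dominate observed murmur prevalence in an
        # unselected cohort; range chosen to put murmur grade >= 2 near the
        # ~13% participant-level rate such cohorts report
        g = rng.uniform(0.5, 3.2)
        sys_g = np.maximum(sys_g, g * np.array([0.8, 1.0, 0.5, 0.3]))
    if ar_g >= 3:
        g = 0.5 * (ar_g - 2.0)
        dia_g = np.maximum(dia_g, g * np.array([1.0, 0.7, 0.4, 0.2]))
    if ms_g >= 1:
        dia_g = np.maximum(dia_g, 0.9 * ms_g * np.array([0.2, 0.2, 0.4, 1.0]))
    return sys_g, dia_g


def _draw_ordinal(rng, pmf):
    return int(rng.choice(len(pmf), p=pmf))


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns ``(participants, truth)``. Identical config (including seed)
    yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    seed_seq = np.random.SeedSequence(config.seed + 1)

    truth = GroundTruth({}, {}, {}, {}, {}, {}, {}, {}, {})
    participants = []

    # full grade distributions consistent with the configured >=threshold rates
    def ar_pmf():
        p3, p4 = 0.70 * config.p_ar3, 0.30 * config.p_ar3
        rest = 1.0 - p3 - p4
        return [0.40 * rest, 0.35 * rest, 0.25 * rest, p3, p4]

    def mr_pmf():
        p3, p4 = 0.75 * config.p_mr3, 0.25 * config.p_mr3
        rest = 1.0 - p3 - p4
        return [0.30 * rest, 0.40 * rest, 0.30 * rest, p3, p4]

    def ms_pmf():
        p = config.p_ms
        return [1.0 - p, 0.65 * p, 0.25 * p, 0.10 * p]

    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        is_as = rng.random() < config.p_as
        avpg = _draw_avpg(rng, is_as)
        as_g = as_grade_from_avpg(avpg)
        ar_g = _draw_ordinal(rng, ar_pmf())
        mr_g = _draw_ordinal(rng, mr_pmf())
        ms_g = _draw_ordinal(rng, ms_pmf())
        innocent = rng.random() < config.p_innocent_murmur
        sys_g, dia_g = _true_position_grades(rng, avpg, as_g, ms_g, ar_g, mr_g, innocent)
        true_g = np.maximum(sys_g, dia_g)

        any_vhd = (as_g >= 1) or (ms_g >= 1) or (ar_g >= 3) or (mr_g >= 3)
        heart_rate = float(np.clip(
            rng.normal(64.5, 9.0) + (config.heart_rate_shift_vhd_bpm if any_vhd else 0.0),
            48.0, 100.0))
        age = float(np.clip(rng.normal(62.6, 9.5) + (config.age_shift_vhd_y if any_vhd else 0.0), 40, 99))
        p_female = 0.55 - (0.20 if as_g >= 1 else 0.0)
        female = bool(rng.random() < p_female)

        sev = max(as_g >= 1, ms_g >= 1) * 1.0 + 0.5 * max(ar_g >= 3, mr_g >= 3)
        b_rest = bool(rng.random() < min(0.02 + 0.10 * sev, 0.9))
        b_level = bool(rng.random() < min(0.05 + 0.14 * sev, 0.9))
        b_uphill = bool(rng.random() < min(0.15 + 0.15 * sev, 0.9))
        mmrc = int(np.clip(rng.poisson(0.3 + 0.8 * sev), 0, 4))

        clinical = {
            "age": age,
            "gender_female": int(female),
            "heart_rate": heart_rate,
            "breathless_rest": int(b_rest),
            "breathless_level": int(b_level),
            "breathless_uphill": int(b_uphill),
            "mmrc": mmrc,
        }
        for var, rate in config.missingness.items():
            if var in clinical and rng.random() < rate:
                clinical[var] = np.nan

        recs = []
        for pos in range(1, 5):
            noisy = bool(rng.random() < config.noise_flag_probs[pos - 1])
            child_seed = seed_seq.spawn(1)[0]
            wav, onsets, states = synthesize_pcg(
                heart_rate, float(sys_g[pos - 1]), float(dia_g[pos - 1]),
                config.sample_rate_hz, config.duration_s, child_seed, noisy=noisy)
            g1 = int(np.clip(np.round(true_g[pos - 1] + rng.normal(0, config.annotator_noise_sd)), 0, 6))
            g2 = int(np.clip(np.round(true_g[pos - 1] + rng.normal(0, config.annotator_noise_sd)), 0, 6))
            recs.append(PcgRecording(pid, pos, wav, config.sample_rate_hz,
                                     (g1, g2), (noisy, noisy)))
            truth.s1_onsets[(pid, pos)] = onsets
            truth.states[(pid, pos)] = states

        participants.append(ParticipantRecord(pid, recs, as_g, ms_g, ar_g, mr_g, avpg, clinical))
        truth.true_grades[pid] = true_g
        truth.avpg[pid] = avpg
        truth.as_grade[pid] = as_g
        truth.ms_grade[pid] = ms_g
        truth.ar_grade[pid] = ar_g
        truth.mr_grade[pid] = mr_g
        truth.heart_rate_bpm[pid] = heart_rate

    return participants, truth


def _states_to_runs(states: np.ndarray):
    """Run-length encode a per-sample state vector as (state, start) pairs."""
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states.astype(int))) + 1
    starts = np.concatenate([[0], change])
    return [[int(states[s]), int(s)] for s in starts]


def write_cohort(participants, truth: GroundTruth, out_dir, write_audio: bool = True):
    """Write WAV files plus manifest/echo/clinical CSVs and ground-truth JSON."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man_rows, echo_rows, clin_rows = [], [], []
    gt = {"s1_onsets": {}, "state_runs": {}}
    for part in participants:
        for rec in part.recordings:
            wav_name = f"{part.participant_id}_{rec.position}.wav"
            if write_audio:
                pio.write_wav(out / wav_name, rec.samples, rec.sample_rate_hz)
            man_rows.append({
                "participant_id": part.participant_id,
                "position": rec.position,
                "wav_path": wav_name,
                "annotator1_grade": rec.annotator_grades[0],
                "annotator2_grade": rec.annotator_grades[1],
                "annotator1_noise": int(rec.noise_flags[0]),
                "annotator2_noise": int(rec.noise_flags[1]),
            })
            key = f"{part.participant_id}_{rec.position}"
            gt["s1_onsets"][key] = [int(v) for v in truth.s1_onsets[(part.participant_id, rec.position)]]
            gt["state_runs"][key] = _states_to_runs(truth.states[(part.participant_id, rec.position)])
        echo_rows.append({
            "participant_id": part.participant_id,
            "AS": part.as_grade, "MS": part.ms_grade,
            "AR": part.ar_grade, "MR": part.mr_grade,
            "avpg_mean": part.avpg_mean,
        })
        clin_rows.append({"participant_id": part.participant_id, **part.clinical})

    import pandas as pd
    pd.DataFrame(man_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(echo_rows).to_csv(out / "echo.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(out / "clinical.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    return out
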