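"""WAV and cohort-table I/O.

Audio contract: 16-bit PCM mono WAV. Samples are decoded to reals by
division by 32768. Cohort tables are UTF-8 comma-separated files with a
mandatory header row; missing values are empty strings and are imputed
downstream, never at load time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger("pcgscreen")

PCM16_SCALE = 32768.0


def read_wav(path):
    """Read a mono PCM16 WAV file; returns ``(samples in [-1, 1], rate)``."""
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    return data.astype(float) / PCM16_SCALE, int(rate)


def write_wav(path, samples, sample_rate_hz: int):
    """Write samples in [-1, 1] as mono PCM16."""
    x = np.asarray(samples, dtype=float)
    q = np.clip(np.round(x * PCM16_SCALE), -32768, 32767)
    wavfile.write(path, int(sample_rate_hz), q.astype(np.int16))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "position", "wav_path",
                "annotator1_grade", "annotator2_grade",
                "annotator1_noise", "annotator2_noise"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if not df["position"].isin([1, 2, 3, 4]).all():
        raise ValueError("positions must be 1..4")
    grades = df[["annotator1_grade", "annotator2_grade"]].to_numpy()
    if ((grades < 0) | (grades > 6)).any():
        raise ValueError("annotator grades must lie in 0..6")
    df = df.copy()
    df["murmur_grade"] = grades.mean(axis=1)
    df["is_noisy"] = (df["annotator1_noise"].astype(bool) | df["annotator2_noise"].astype(bool))
    return df


def load_participants(cohort_dir):
    """Reconstruct ParticipantRecord objects from a cohort directory
    (manifest.csv + echo.csv + clinical.csv + WAV files), e.g. one written
    by the simulator. Corrupt or unreadable WAVs drop the participant with
    a log line."""
    from .synth import ParticipantRecord, PcgRecording

    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.csv")
    echo = pd.read_csv(cohort_dir / "echo.csv").set_index("participant_id")
    clinical = pd.read_csv(cohort_dir / "clinical.csv").set_index("participant_id")

    participants = []
    for pid, grp in manifest.sort_values(["participant_id", "position"]).groupby(
            "participant_id", sort=True):
        try:
            recs = []
            for _, row in grp.iterrows():
                samples, fs = read_wav(cohort_dir / row["wav_path"])
                recs.append(PcgRecording(
                    pid, int(row["position"]), samples, fs,
                    (int(row["annotator1_grade"]), int(row["annotator2_grade"])),
                    (bool(row["annotator1_noise"]), bool(row["annotator2_noise"]))))
        except (ValueError, FileNotFoundError, OSError) as exc:
            log.warning("participant %s dropped: %s", pid, exc)
            continue
        if pid not in echo.index:
            log.warning("participant %s has no echo row; dropped", pid)
            continue
        e = echo.loc[pid]
        clin = clinical.loc[pid].to_dict() if pid in clinical.index else {}
        participants.append(ParticipantRecord(
            pid, recs, int(e["AS"]), int(e["MS"]), int(e["AR"]), int(e["MR"]),
            float(e["avpg_mean"]), clin))
    return participants


def load_cohort(manifest_path, echo_path, clinical_path=None):
    """Join manifest, echocardiography, and clinical tables per participant.

    Returns ``(manifest, participant_table, report)``. Participants whose
    four recordings are all flagged noisy are marked ``excluded``;
    manifest/echo id mismatches are listed in the reconciliation report and
    excluded from disease analyses. Row order of the input CSVs does not
    affect the result.
    """
    manifest = read_manifest(manifest_path).sort_values(
        ["participant_id", "position"]).reset_index(drop=True)
    echo = pd.read_csv(echo_path).sort_values("participant_id").reset_index(drop=True)

    noise_per_pid = manifest.groupby("participant_id")["is_noisy"].agg(["sum", "count"])
    all_noisy_ids = set(noise_per_pid.index[noise_per_pid["sum"] == noise_per_pid["count"]])

    man_ids = set(manifest["participant_id"])
    echo_ids = set(echo["participant_id"])
    unmatched = sorted(man_ids - echo_ids)
    for pid in unmatched:
        log.warning("participant %s present in manifest but not echo; excluded from VHD analyses", pid)

    table = echo[echo["participant_id"].isin(man_ids)].copy()
    table["excluded_all_noisy"] = table["participant_id"].isin(all_noisy_ids)
    for pid in sorted(all_noisy_ids):
        log.info("participant %s excluded: noise in all four recordings", pid)

    if clinical_path is not None:
        clinical = pd.read_csv(clinical_path).sort_values("participant_id").reset_index(drop=True)
        table = table.merge(clinical, on="participant_id", how="left")

    report = {
        "n_manifest_participants": len(man_ids),
        "n_echo_participants": len(echo_ids),
        "unmatched_ids": unmatched,
        "n_all_noisy_excluded": len(all_noisy_ids),
        "n_analyzed": int((~table["excluded_all_noisy"]).sum()),
    }
    return manifest, table.reset_index(drop=True), report
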