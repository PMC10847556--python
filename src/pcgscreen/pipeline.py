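"""End-to-end orchestration: cohort -> segmentation -> features -> murmur
net -> multiposition gradient model -> screening, with the eightfold
participant-level cross-validation harness and a held-out set.

The expensive stage is murmur-net training, so the block dataset (segmented
and featurized recordings) is built once and reused across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import avpg as avpg_mod
from . import features as feat_mod
from . import metrics as met
from . import murmur_net as net_mod
from . import screening as scr_mod
from . import segmentation as seg_mod


@dataclass
class PipelineConfig:
    seed: int = 0
    n_folds: int = 8
    holdout_frac: float = 0.10
    epochs_cv: int = 4          # per-fold murmur-net epochs (desk scale)
    epochs_final: int = 8       # final dev-set model for the holdout check
    batch_size: int = 128


@dataclass
class RecordingBlocks:
    participant_id: str
    position: int
    noisy: bool
    murmur_grade: float
    blocks: list                # list of (13, 200) matrices


@dataclass
class BlockDataset:
    recordings: list            # RecordingBlocks
    excluded_all_noisy: list    # participant ids
    unusable_recordings: int
    participants: dict          # pid -> ParticipantRecord

    def by_participant(self):
        out = {}
        for rec in self.recordings:
            out.setdefault(rec.participant_id, []).append(rec)
        return out


def build_block_dataset(participants, sample_rate_hz: int,
                        emission_model=None) -> BlockDataset:
    """Segment every usable recording and extract 13 x 200 feature blocks."""
    if emission_model is None:
        emission_model = seg_mod.default_emission_model(sample_rate_hz)
    recs_out, excluded = [], []
    unusable = 0
    pmap = {}
    for part in participants:
        pmap[part.participant_id] = part
        if part.all_noisy:
            excluded.append(part.participant_id)
            continue
        seg_results = seg_mod.segment_participant(
            [(r.samples, r.is_noisy) for r in part.recordings],
            sample_rate_hz, emission_model)
        for rec, seg in zip(part.recordings, seg_results):
            blocks = seg_mod.extract_blocks(seg.cycle_starts)
            fblocks = feat_mod.block_features(
                rec.samples, blocks, sample_rate_hz,
                recording_id=f"{part.participant_id}_{rec.position}")
            if not fblocks:
                unusable += 1
                continue
            recs_out.append(RecordingBlocks(
                part.participant_id, rec.position, rec.is_noisy,
                rec.murmur_grade, [fb.matrix for fb in fblocks]))
    return BlockDataset(recs_out, excluded, unusable, pmap)


def _training_arrays(dataset: BlockDataset, pids):
    """Blocks + labels for the non-noisy recordings of the given participants.

    Every block inherits its recording's murmur grade as label."""
    pidset = set(pids)
    blocks, labels = [], []
    for rec in dataset.recordings:
        if rec.participant_id in pidset and not rec.noisy:
            blocks.extend(rec.blocks)
            labels.extend([rec.murmur_grade] * len(rec.blocks))
    return blocks, labels


def train_fold_net(dataset: BlockDataset, train_pids, epochs: int,
                   seed: int, batch_size: int = 128) -> net_mod.MurmurNet:
    blocks, labels = _training_arrays(dataset, train_pids)
    blocks, labels = net_mod.balance_training_set(blocks, labels, seed)
    cfg = net_mod.NetConfig(epochs=epochs, seed=seed, batch_size=batch_size)
    return net_mod.train(blocks, labels, cfg)


def predict_participants(net, dataset: BlockDataset, pids):
    """Per-participant grade 4-vectors and noise bits; noisy positions
    contribute grade 0."""
    by_pid = dataset.by_participant()
    out = {}
    for pid in pids:
        grades = np.zeros(4)
        noise = np.ones(4, dtype=int)  # positions without usable blocks count as noisy
        for rec in by_pid.get(pid, []):
            noise[rec.position - 1] = int(rec.noisy)
            if not rec.noisy:
                g = net_mod.predict_blocks(net, rec.blocks)
                grades[rec.position - 1] = float(np.median(g))
        out[pid] = (grades, noise)
    return out


def _participant_table(dataset: BlockDataset, preds: dict, avpg_scores: dict):
    rows = []
    for pid, (grades, noise) in preds.items():
        part = dataset.participants[pid]
        masked = np.where(noise > 0, 0.0, grades)
        rows.append({
            "participant_id": pid,
            "AS": part.as_grade, "MS": part.ms_grade,
            "AR": part.ar_grade, "MR": part.mr_grade,
            "avpg_mean": part.avpg_mean,
            "max_grade": float(masked.max()),
            "mitral_grade": float(masked[3]),
            "avpg_pred": avpg_scores.get(pid, np.nan),
            **part.clinical,
        })
    return pd.DataFrame(rows)


def cv_run(participants, config: PipelineConfig, dataset: BlockDataset | None = None,
           sample_rate_hz: int | None = None):
    """Run the full cross-validated screening analysis on a cohort.

    Returns a report dict: exclusion reconciliation, per-definition joint
    screening metrics, the selected multiposition model, clinical-model
    AUCs, and the holdout check.
    """
    if dataset is None:
        if sample_rate_hz is None:
            sample_rate_hz = participants[0].recordings[0].sample_rate_hz
        dataset = build_block_dataset(participants, sample_rate_hz)

    all_pids = [p.participant_id for p in participants]
    analyzed = [pid for pid in all_pids if pid not in set(dataset.excluded_all_noisy)]
    as_pos = [dataset.participants[pid].as_grade >= 1 for pid in analyzed]
    plan = scr_mod.make_folds(analyzed, as_pos, config.n_folds,
                              config.holdout_frac, config.seed)
    dev_pids = [pid for pid in analyzed if pid in plan.fold_of]

    # --- out-of-fold murmur predictions -----------------------------------
    oof = {}
    for k in range(config.n_folds):
        val = plan.fold_ids(k)
        train_pids = [pid for pid in dev_pids if plan.fold_of[pid] != k]
        net = train_fold_net(dataset, train_pids, config.epochs_cv,
                             config.seed + 100 + k, config.batch_size)
        oof.update(predict_participants(net, dataset, val))

    # --- multiposition AVPG model -----------------------------------------
    mg = np.vstack([oof[pid][0] for pid in dev_pids])
    noise = np.vstack([oof[pid][1] for pid in dev_pids])
    y_avpg = np.array([dataset.participants[pid].avpg_mean for pid in dev_pids])
    sel = avpg_mod.stepwise_select(mg, noise, y_avpg)
    avpg_scores = {}
    for k in range(config.n_folds):
        val = plan.fold_ids(k)
        tr = [pid for pid in dev_pids if plan.fold_of[pid] != k]
        tr_i = [dev_pids.index(pid) for pid in tr]
        refit = avpg_mod.fit_ols(sel.spec.terms, mg[tr_i], noise[tr_i], y_avpg[tr_i])
        for pid in val:
            avpg_scores[pid] = avpg_mod.evaluate(refit.spec, *oof[pid])

    table = _participant_table(dataset, oof, avpg_scores)
    table["symptomatic"] = [scr_mod.symptomatic_flag(r) for _, r in table.iterrows()]

    # --- joint screening ---------------------------------------------------
    fold_of = plan.fold_of
    screening_report = {}
    for definition in (1, 2, 3):
        labels = np.array([
            scr_mod.joint_positive(r["AS"], r["MS"], r["AR"], r["MR"],
                                   r["symptomatic"], definition)
            for _, r in table.iterrows()])
        scores = table["max_grade"].to_numpy()
        pid_arr = table["participant_id"].to_numpy()
        decisions = np.zeros(len(table), dtype=bool)
        fold_aucs = []
        for k in range(config.n_folds):
            in_val = np.array([fold_of.get(p) == k for p in pid_arr])
            in_tr = np.array([fold_of.get(p, -1) not in (k, -1) for p in pid_arr])
            if labels[in_tr].any() and not labels[in_tr].all():
                thr = scr_mod.select_threshold(scores[in_tr], labels[in_tr])
            else:
                thr = 0.5
            decisions[in_val] = scores[in_val] >= thr
            if labels[in_val].any() and not labels[in_val].all():
                fold_aucs.append(met.auc(scores[in_val], labels[in_val]))
        in_dev = np.array([p in fold_of for p in pid_arr])
        pooled_auc = met.auc(scores[in_dev], labels[in_dev]) if labels[in_dev].any() else np.nan
        det = decisions & labels & in_dev
        sens = det.sum() / max((labels & in_dev).sum(), 1)
        spec = ((~decisions) & (~labels) & in_dev).sum() / max(((~labels) & in_dev).sum(), 1)
        per_disease = {}
        for name, col, cut in (("AS", "AS", 1), ("MS", "MS", 1), ("AR", "AR", 3), ("MR", "MR", 3)):
            case = (table[col].to_numpy() >= cut) & in_dev
            per_disease[name] = {
                "n_cases": int(case.sum()),
                "detected": int((decisions & case).sum()),
            }
        screening_report[definition] = {
            "auc_pooled": float(pooled_auc),
            "fold_auc_ci": met.fold_ci(fold_aucs) if len(fold_aucs) >= 2 else None,
            "sensitivity": float(sens),
            "specificity": float(spec),
            "per_disease": per_disease,
        }

    # --- clinical-variable models -----------------------------------------
    audio_col = {"AR>=3": "max_grade", "MR>=3": "mitral_grade",
                 "AS>=1": "avpg_pred", "MS>=1": "max_grade"}
    target_def = {"AR>=3": ("AR", 3), "MR>=3": ("MR", 3),
                  "AS>=1": ("AS", 1), "MS>=1": ("MS", 1)}
    clinical_report = {}
    in_dev_mask = table["participant_id"].isin(fold_of).to_numpy()
    for target, (col, cut) in target_def.items():
        work = table[in_dev_mask].copy()
        work["murmur"] = work[audio_col[target]]
        work[target] = (work[col] >= cut).astype(float)
        if work[target].sum() < 4:
            clinical_report[target] = {"skipped": "too few cases"}
            continue
        probs = np.full(len(work), np.nan)
        try:
            for k in range(config.n_folds):
                in_val = work["participant_id"].map(fold_of).to_numpy() == k
                fit = scr_mod.fit_clinical_model(target, work[~in_val])
                probs[in_val] = scr_mod.predict_clinical(fit, work[in_val])
            auc_clin = met.auc(probs, work[target].to_numpy() > 0)
            auc_audio = met.auc(work["murmur"].to_numpy(), work[target].to_numpy() > 0)
            clinical_report[target] = {"auc_clinical": float(auc_clin),
                                       "auc_audio_only": float(auc_audio)}
        except (RuntimeError, ValueError) as exc:
            clinical_report[target] = {"skipped": str(exc)}

    # --- holdout check -----------------------------------------------------
    final_net = train_fold_net(dataset, dev_pids, config.epochs_final,
                               config.seed + 999, config.batch_size)
    hold_preds = predict_participants(final_net, dataset, plan.holdout)
    holdout_report = {"n": len(plan.holdout)}
    if plan.holdout:
        hmax = np.array([np.where(n > 0, 0.0, g).max() for g, n in
                         (hold_preds[p] for p in plan.holdout)])
        hsten = np.array([dataset.participants[p].as_grade >= 1
                          or dataset.participants[p].ms_grade >= 1
                          for p in plan.holdout])
        holdout_report["n_stenosis"] = int(hsten.sum())
        if hsten.any() and not hsten.all():
            holdout_report["stenosis_auc"] = float(met.auc(hmax, hsten))

    counts = {
        "n_input": len(all_pids),
        "n_excluded_all_noisy": len(dataset.excluded_all_noisy),
        "n_analyzed": len(analyzed),
        "n_dev": len(dev_pids),
        "n_holdout": len(plan.holdout),
        "n_unusable_recordings": dataset.unusable_recordings,
    }
    assert counts["n_input"] == counts["n_analyzed"] + counts["n_excluded_all_noisy"]
    assert counts["n_analyzed"] == counts["n_dev"] + counts["n_holdout"]

    return {
        "counts": counts,
        "avpg_model": sel.spec.to_json_dict(),
        "screening": screening_report,
        "clinical": clinical_report,
        "holdout": holdout_report,
        "seed": config.seed,
    }


def murmur_holdout_eval(dataset: BlockDataset, truth, epochs: int = 15,
                        holdout_frac: float = 0.2, seed: int = 0,
                        batch_size: int = 128):
    """Train once, evaluate murmur-grade recovery on held-out participants.

    Returns a dict with held-out Spearman correlation between predicted and
    true recording-level grades and the AUC for detecting true grade >= 2.
    """
    pids = sorted(dataset.participants)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    n_hold = int(round(holdout_frac * len(pids)))
    hold = {pids[i] for i in order[:n_hold]}
    train_pids = [p for p in pids if p not in hold]

    net = train_fold_net(dataset, train_pids, epochs, seed, batch_size)

    preds, trues = [], []
    for rec in dataset.recordings:
        if rec.participant_id in hold and not rec.noisy:
            g = float(np.median(net_mod.predict_blocks(net, rec.blocks)))
            preds.append(g)
            trues.append(truth.true_grades[rec.participant_id][rec.position - 1])
    preds = np.asarray(preds)
    trues = np.asarray(trues)
    rho = float(_sstats.spearmanr(preds, trues).statistic)
    labels = trues >= 2.0
    out = {"spearman": rho, "n_holdout_recordings": len(preds),
           "n_grade2": int(labels.sum())}
    if labels.any() and not labels.all():
        out["auc_grade2"] = float(met.auc(preds, labels))
    return out, net
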