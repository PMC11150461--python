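"""End-to-end orchestration of the synergy analysis.

Stages: (optional) simulate -> preprocess -> tVAF curves -> NoS/NoSoA ->
reorder to a reference participant -> pairwise inter-participant
similarity -> cross-participant and cross-task reconstruction with
randomized nulls -> shared-synergy counts.  Every stage's result is
returned in memory and written as a tidy table; a JSON run report records
the configuration and seeds needed to reproduce the tables byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import reconstruction, selection, shared, similarity
from .factorization import TvafCurve, tvaf_curve
from .io import PipelineConfig, load_manifest, write_table
from .preprocessing import EnvelopeMatrix, assemble, process_trial
from .selection import NosResult
from .synthetic import GeneratorConfig, RawTrial, generate_dataset, write_dataset

__all__ = ["run_pipeline", "preprocess_dataset", "extract_curves",
            "selection_table"]

log = logging.getLogger("emgsyn")


def _stable_offset(*parts: str) -> int:
    """Run-independent seed offset from string keys (crc32, not hash())."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % 100000


def preprocess_dataset(trials: list[RawTrial], muscle_names: list[str],
                       config: PipelineConfig) -> dict[str, dict[str, EnvelopeMatrix]]:
    """Raw trials -> per-participant, per-task envelope matrices."""
    grouped: dict[str, dict[str, list[np.ndarray]]] = defaultdict(lambda: defaultdict(list))
    for tr in sorted(trials, key=lambda t: (t.participant_id, t.task_id, t.trial_id)):
        env = process_trial(tr.signals, tr.events, tr.sampling_rate,
                            band=config.band, order=config.filter_order,
                            lowpass=config.lowpass)
        grouped[tr.participant_id][tr.task_id].append(env)
    out = {}
    for pid, by_task in grouped.items():
        out[pid] = assemble(dict(by_task), muscle_names, participant_id=pid)
    return out


def extract_curves(envelopes: dict[str, dict[str, EnvelopeMatrix]],
                   config: PipelineConfig) -> dict[tuple[str, str], TvafCurve]:
    curves = {}
    for pid, by_task in sorted(envelopes.items()):
        for task, em in sorted(by_task.items()):
            log.info("tVAF curve: participant %s task %s", pid, task)
            curves[(pid, task)] = tvaf_curve(
                em.E, restarts=config.restarts,
                seed=config.seed + _stable_offset(pid, task),
                k_max=config.k_max, max_iter=config.max_iter, tol=config.tol,
                solver=config.solver, participant_id=pid, task_id=task)
    return curves


def selection_table(curves: dict[tuple[str, str], TvafCurve],
                    config: PipelineConfig
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], NosResult], int]:
    """Per participant x task NoS plus the study-wide NoSoA and CoV summary."""
    results = {key: selection.select_nos(c, config.tvaf_threshold,
                                         config.increment_threshold)
               for key, c in curves.items()}
    n_overall = selection.nosoa(results.values())
    rows = []
    for (pid, task), res in sorted(results.items()):
        res.tvaf_at_nosoa = float(curves[(pid, task)].tvaf_by_k[
            min(n_overall, curves[(pid, task)].k_max) - 1])
        rows.append(dict(participant=pid, task=task, nos=res.nos,
                         tvaf_at_nos=res.tvaf_at_nos,
                         tvaf_at_nosoa=res.tvaf_at_nosoa,
                         tvaf_at_one=float(curves[(pid, task)].tvaf_by_k[0]),
                         criterion1_k=res.criterion1_k,
                         fallback=res.fallback))
    table = pd.DataFrame(rows)
    return table, results, n_overall


def cov_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-task coefficient of variation, mean and SD of NoS and tVAF values."""
    rows = []
    for task, grp in table.groupby("task"):
        row = dict(task=task)
        for col, label in (("nos", "nos"), ("tvaf_at_nos", "tvaf_nos"),
                           ("tvaf_at_nosoa", "tvaf_nosoa")):
            vals = grp[col].to_numpy(dtype=float)
            row[f"cov_{label}"] = selection.coefficient_of_variation(vals)
            row[f"mean_{label}"] = float(np.mean(vals))
            row[f"sd_{label}"] = float(np.std(vals, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tables + run report under ``config.outdir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        gen_cfg = GeneratorConfig(**config.simulate)
        trials, gt = generate_dataset(gen_cfg, seed=gen_cfg.seed)
        data_dir = outdir / "synthetic_data"
        manifest = write_dataset(trials, gt, data_dir)
        muscles = gt.muscle_names
        sampling_rate = gen_cfg.sampling_rate
        log.info("simulated %d trials -> %s", len(trials), data_dir)
    elif config.manifest is not None:
        trials, muscles, sampling_rate = load_manifest(config.manifest)
        manifest = Path(config.manifest)
    else:
        raise ValueError("config needs either a manifest path or a simulate block")
    config.validate(muscles=len(muscles))

    envelopes = preprocess_dataset(trials, muscles, config)
    curves = extract_curves(envelopes, config)

    curve_rows = [dict(participant=pid, task=task, k=k + 1,
                       tvaf=float(c.tvaf_by_k[k]))
                  for (pid, task), c in sorted(curves.items())
                  for k in range(c.k_max)]
    write_table(pd.DataFrame(curve_rows), outdir / "tvaf_curves.tsv")

    sel_table, nos_results, n_overall = selection_table(curves, config)
    write_table(sel_table, outdir / "nos_selection.tsv")
    cov = cov_summary(sel_table)
    write_table(cov, outdir / "cov_summary.tsv")
    log.info("NoSoA = %d", n_overall)

    participants = sorted({pid for pid, _ in curves})
    tasks = sorted({task for _, task in curves})
    reference = config.reference_participant or participants[0]
    block = config.points_per_phase if config.rmax_on_concatenated else None

    pair_tables, summary_tables, recon_tables, null_tables = [], [], [], []
    reordered_by_task = {}
    for task in tasks:
        decomps = {pid: curves[(pid, task)][n_overall] for pid in participants}
        if len(decomps) < 2:
            continue
        reordered, _perms = similarity.reorder_to_reference(decomps, reference)
        reordered_by_task[task] = reordered
        pairs, summary = similarity.pairwise_interparticipant(
            reordered, alpha=config.alpha,
            cossim_threshold=config.cossim_threshold,
            rmax_threshold=config.rmax_threshold,
            max_lag_fraction=config.max_lag_fraction, block_length=block)
        pairs.insert(0, "task", task)
        summary.insert(0, "task", task)
        pair_tables.append(pairs)
        summary_tables.append(summary)

        envs = {pid: envelopes[pid][task].E for pid in participants}
        recon = reconstruction.cross_participant_study(
            reordered, envs, config.max_lag_fraction, block)
        recon.insert(0, "task", task)
        recon_tables.append(recon)
        for pid in participants:
            others = [reordered[q] for q in participants if q != pid]
            for part in ("W", "C"):
                null = reconstruction.randomized_null(
                    reordered[pid], envs[pid], others, fixed_part=part,
                    seed=config.seed + _stable_offset(task, pid, part),
                    max_lag_fraction=config.max_lag_fraction,
                    block_length=block)
                null.insert(0, "task", task)
                null["target"] = pid
                null_tables.append(null)

    if pair_tables:
        write_table(pd.concat(pair_tables, ignore_index=True),
                    outdir / "interparticipant_pairs.tsv")
        write_table(pd.concat(summary_tables, ignore_index=True),
                    outdir / "interparticipant_summary.tsv")
        write_table(pd.concat(recon_tables, ignore_index=True),
                    outdir / "cross_participant_reconstruction.tsv")
        write_table(pd.concat(null_tables, ignore_index=True),
                    outdir / "cross_participant_randomized_null.tsv")

    # shared synergies + cross-task reconstruction, per participant
    shared_rows, xtask_tables, xnull_tables = [], [], []
    if len(tasks) >= 2:
        for pid in participants:
            decomps_oa = {task: curves[(pid, task)][n_overall] for task in tasks}
            decomps_ind = {task: curves[(pid, task)][nos_results[(pid, task)].nos]
                           for task in tasks}
            results = shared.shared_oa(decomps_oa, participant_id=pid)
            results += shared.shared_ind(decomps_ind, participant_id=pid)
            for r in results:
                shared_rows.append(dict(
                    participant=pid, method=r.method, task1=r.task_pair[0],
                    task2=r.task_pair[1], k1=r.k1, k2=r.k2,
                    n_shared=r.n_shared, pct_shared=r.pct_shared))
            if len(tasks) == 3:
                for method, dec in (("sharedOA", decomps_oa),
                                    ("sharedIND", decomps_ind)):
                    res = [r for r in results if r.method == method]
                    triples = shared.all_task_shared(res)
                    shared_rows.append(dict(
                        participant=pid, method=method, task1="all", task2="all",
                        k1=np.nan, k2=np.nan, n_shared=len(triples),
                        pct_shared=np.nan))
            envs = {task: envelopes[pid][task].E for task in tasks}
            xt = shared.cross_task_reconstruction(
                decomps_oa, envs, config.max_lag_fraction, block)
            xt.insert(0, "participant", pid)
            xtask_tables.append(xt)
            for task in tasks:
                others = [decomps_oa[t] for t in tasks if t != task]
                for part in ("W", "C"):
                    null = reconstruction.randomized_null(
                        decomps_oa[task], envs[task], others, fixed_part=part,
                        seed=config.seed + _stable_offset("xt", pid, task, part),
                        max_lag_fraction=config.max_lag_fraction,
                        block_length=block)
                    null.insert(0, "participant", pid)
                    null.insert(1, "task", task)
                    xnull_tables.append(null)
        write_table(pd.DataFrame(shared_rows), outdir / "shared_synergies.tsv")
        write_table(pd.concat(xtask_tables, ignore_index=True),
                    outdir / "cross_task_reconstruction.tsv")
        write_table(pd.concat(xnull_tables, ignore_index=True),
                    outdir / "cross_task_randomized_null.tsv")

    import scipy

    from . import __version__
    report = dict(config=config.to_json(), nosoa=n_overall,
                  manifest=str(manifest), participants=participants,
                  tasks=tasks, reference_participant=reference,
                  n_trials=len(trials), sampling_rate=sampling_rate,
                  versions=dict(emgsyn=__version__, numpy=np.__version__,
                                scipy=scipy.__version__, pandas=pd.__version__))
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))

    return dict(envelopes=envelopes, curves=curves, selection=sel_table,
                nos_results=nos_results, nosoa=n_overall, cov=cov,
                reordered=reordered_by_task,
                shared=pd.DataFrame(shared_rows) if shared_rows else None)
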