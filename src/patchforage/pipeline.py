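"""End-to-end orchestration: synthesize, simulate, fit, summarize, link."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from patchforage import agents, models, neurochem, stats
from patchforage.io import RunConfig, records_to_frame, write_trials
from patchforage.task import PatchDynamicsParams

__all__ = ["run_pipeline", "participant_seed"]

log = logging.getLogger("patchforage")


def participant_seed(master_seed: int, participant: int) -> int:
    """Deterministic per-participant stream seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, participant]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run the full synthetic study once.

    Generates a cohort with planted effects, simulates each participant's
    session, fits the fixed-scale multiplicative subjective-value model,
    assembles decision variables, computes E/I profiles after quality
    control, and runs the gated link hierarchy.  Returns the report dict;
    if ``out_dir`` is given, trial tables (TSV), metabolite and decision
    variable tables (CSV), and the JSON report are written there.
    """
    rng = np.random.default_rng(config.seed)
    task_params = PatchDynamicsParams(n_trials=config.n_trials, **config.task_params)
    cohort_spec = agents.CohortSpec(
        n_participants=config.n_participants,
        planted_effects=[
            agents.PlantedEffect(e["region"], e["trait"], e["r"])
            for e in config.planted_effects
        ],
    )
    agent_list, metabolites, latents = agents.generate_cohort(cohort_spec, rng)
    log.info("generated cohort of %d participants", config.n_participants)

    spec = models.ValueModelSpec.su_multiplicative(
        omega_mult=config.omega_mult, n_starts=config.n_starts
    )
    dv_rows = []
    trial_tables = {}
    for i, agent_params in enumerate(agent_list):
        p_rng = np.random.default_rng(participant_seed(config.seed, i))
        trials = agents.simulate_participant(
            agent_params,
            task_params,
            p_rng,
            replicate_side_bias_bug=config.replicate_side_bias_bug,
        )
        trial_tables[i] = trials
        data = models.prepare_choice_data(trials)
        fit = models.fit_model(data, spec, p_rng)
        dv = stats.compute_decision_variables(trials, fit)
        row = dv.to_dict()
        row["participant"] = i
        row["nll"] = fit.nll
        row["bic"] = fit.bic
        dv_rows.append(row)
        log.info("participant %d: NLL=%.1f alpha=%.3f gamma=%.3f",
                 i, fit.nll, fit.params.alpha, fit.params.gamma)
    dvs = pd.DataFrame(dv_rows).set_index("participant")

    flagged, excluded = neurochem.qc_filter(metabolites)
    kept = metabolites[~metabolites["participant"].isin(excluded)]
    ei, gaba, glu = neurochem.ei_profiles(kept)
    dvs_link = dvs.loc[ei.index]

    link = neurochem.run_testing_hierarchy(
        dvs_link, ei, gaba, glu,
        neurochem.LinkConfig(gate_alpha=config.gate_alpha),
    )

    report = {
        "schema_version": 1,
        "config": config.to_dict(),
        "n_excluded_qc": len(excluded),
        "group": {
            "mean_pla": float(np.nanmean(dvs["mean_pla"])),
            "mean_leave_count": float(np.mean([
                (t["patch_choice"] == "leave").sum() for t in trial_tables.values()
            ])),
            "mean_pct_correct": float(np.nanmean(dvs["pct_correct"])),
            "mean_nb_share": float(np.nanmean(dvs["nb_share"])),
        },
        "link": link,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, trials in trial_tables.items():
            write_trials(trials, out / f"participant_{i:03d}.tsv")
        metabolites.to_csv(out / "metabolites.csv", index=False)
        dvs.to_csv(out / "decision_variables.csv")
        with (out / "report.json").open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
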