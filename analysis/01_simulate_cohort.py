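#!/usr/bin/env python
"""Generate the study cohort: 15 patients, 29 leads, realistic noise.

Writes the cohort's file set under results/cohort/ — observed landmarks
(single noisy reading), the exact landmarks, three repeated segmentation
campaigns, implanted active-contact targets, the noiseless targets, the
reconstructed lead trajectories, and a manifest echoing the configuration.
Subsequent analysis steps consume these files through the documented CSV
dialects.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from vimtarget.io import write_landmarks, write_leads, write_targets
from vimtarget.landmarks import disassemble_feature_vector, validate_landmark_set
from vimtarget.synthetic import GeneratorConfig, generate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-patients", type=int, default=15)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    out = args.results_dir / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        GeneratorConfig(n_patients=args.n_patients, n_unilateral=1, seed=args.seed)
    )

    observed_sets = [
        dataclasses.replace(
            disassemble_feature_vector(x, patient_id=pid, hemisphere=hemi),
            rater_id="OBS", session_id="S1",
        )
        for x, pid, hemi in zip(cohort.observed.X, cohort.observed.patient_ids,
                                cohort.observed.hemispheres)
    ]
    write_landmarks(observed_sets, out / "landmarks.csv", cohort.acpc_by_patient)
    write_landmarks(cohort.clean_sets, out / "clean_landmarks.csv", cohort.acpc_by_patient)
    write_landmarks(cohort.replicas, out / "replicas.csv", cohort.acpc_by_patient)

    import pandas as pd

    def targets_frame(ds):
        return pd.DataFrame({
            "patient_id": ds.patient_ids, "hemisphere": ds.hemispheres,
            "x": ds.Y[:, 0], "y": ds.Y[:, 1], "z": ds.Y[:, 2], "frame": "PC",
            "acpc_length": [cohort.acpc_by_patient[p] for p in ds.patient_ids],
        })

    write_targets(targets_frame(cohort.observed), out / "targets.csv")
    write_targets(targets_frame(cohort.clean), out / "clean_targets.csv")
    write_leads(cohort.leads, out / "leads.csv")
    (out / "manifest.json").write_text(
        json.dumps(cohort.manifest, indent=2, sort_keys=True)
    )

    violations = sum(
        len(validate_landmark_set(s, tolerance_tau=1e-6)) for s in cohort.clean_sets
    )
    print(f"cohort: {cohort.n_leads} leads over {args.n_patients} patients "
          f"(one unilateral), {violations} landmark-constraint violations")
    print(f"files written under {out}/")


if __name__ == "__main__":
    main()
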