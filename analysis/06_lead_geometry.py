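#!/usr/bin/env python
"""Lead placement accuracy: d1 and d2 for every implanted electrode.

Reconstructs each lead's axis from its tip and proximal point, locates the
active contact's centre on the axis, and measures d1 (contact centre to
planned target) and d2 (perpendicular axis-to-target distance) against the
noiseless targets.  d2 <= d1 must hold for every lead since the contact
centre lies on the axis.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from vimtarget.geometry import (
    LeadTrajectory,
    MEDTRONIC_3389,
    accuracy_d1,
    accuracy_d2,
    contact_centers,
)
from vimtarget.io import read_leads, read_targets


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort_dir = args.results_dir / "cohort"
    leads = read_leads(cohort_dir / "leads.csv")
    targets = read_targets(cohort_dir / "clean_targets.csv").set_index(
        ["patient_id", "hemisphere"]
    )
    rows = []
    for row in leads.itertuples():
        t = targets.loc[(row.patient_id, row.hemisphere)]
        planned = np.array([t["x"], t["y"], t["z"]])
        traj = LeadTrajectory(tip_A=np.array([row.ax, row.ay, row.az]),
                              proximal_J=np.array([row.jx, row.jy, row.jz]))
        contact = contact_centers(traj, MEDTRONIC_3389)[row.active_contact_index]
        rows.append({
            "patient_id": row.patient_id, "hemisphere": row.hemisphere,
            "d1_mm": accuracy_d1(contact, planned),
            "d2_mm": accuracy_d2(traj.tip_A, traj.unit_direction_u, planned),
        })
    table = pd.DataFrame(rows)
    out = args.results_dir / "lead_accuracy.csv"
    table.to_csv(out, index=False)
    print(f"{len(table)} leads: d1 median {table['d1_mm'].median():.2f} mm "
          f"[IQR {table['d1_mm'].quantile(.25):.2f}-{table['d1_mm'].quantile(.75):.2f}], "
          f"d2 median {table['d2_mm'].median():.2f} mm")
    assert (table["d2_mm"] <= table["d1_mm"] + 1e-9).all()
    print(f"accuracy table -> {out}")


if __name__ == "__main__":
    main()
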