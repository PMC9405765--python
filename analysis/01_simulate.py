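"""Generate the synthetic study inputs: a clinical cohort and phantom mpMRI
studies.

Writes the cohort table to results/cohort.csv and a handful of example
phantom studies (NIfTI volumes + truth masks + JSON manifest) under
scratch/studies/ for inspection; prints the realized outcome and censoring
rates. The full pipeline regenerates phantoms in memory for every imaging
patient, so only examples are materialized on disk.
"""

import argparse
from pathlib import Path

from mmrecur import io as mio
from mmrecur import synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-example-studies", type=int, default=3)
    args = ap.parse_args()

    cohort = synth.generate_cohort(synth.CohortSpec(seed=args.seed))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    mio.write_cohort(results / "cohort.csv", cohort)

    unc = cohort[cohort["censored"] == 0]
    print(f"cohort: {len(cohort)} patients, {int(cohort['has_imaging'].sum())} with imaging")
    print(f"  uncensored: {len(unc)}  positive rate (uncensored): {unc['outcome'].mean():.3f}")
    print(f"  censoring rate: {cohort['censored'].mean():.3f}")

    out = ROOT / "scratch" / "studies"
    entries = []
    img = cohort[cohort["has_imaging"] == 1].head(args.n_example_studies)
    for i, (_, row) in enumerate(img.iterrows()):
        spec = synth.phantom_spec_for_patient(row, seed=args.seed * 100003 + i)
        study, truth = synth.generate_phantom(spec)
        study.patient_id = row["patient_id"]
        entries.append(mio.write_study(out, study, truth))
        print(
            f"  wrote study {row['patient_id']}: lesion {truth.analytic_volume_mm3:.0f} mm^3 "
            f"({row['tumor_side']}), significant slice {study.annotations.significant_slice}"
        )
    mio.write_manifest(out / "manifest.json", entries)
    print(f"cohort -> {results/'cohort.csv'}; {len(entries)} example studies -> {out}")


if __name__ == "__main__":
    main()
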