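"""Simulate a multi-site prostate MRI cohort.

The generator produces, per tumor: a T2-weighted volume carrying a
grade-dependent texture field and an exactly affine per-institution
intensity effect; embedded fat and muscle reference regions with known
percentile anchors; a co-registered diffusion-weighted series following a
monoexponential decay; and the histology-style metadata (ISUP grade
group, aggressiveness class).

Run:  python examples/01_simulate_cohort.py
"""

from pzrad.synthetic import CohortConfig, generate_cohort

config = CohortConfig()  # six imbalanced institutions, ~90 patients
cohort = generate_cohort(config, seed=1)
manifest = cohort.manifest()

print(f"{len(cohort.tumors)} tumors from {manifest['patient_id'].nunique()} patients\n")
print("tumors per institution:")
print(manifest["site_id"].value_counts().sort_index().to_string(), "\n")
print("grade group distribution:")
print(manifest["grade_group"].value_counts().sort_index().to_string(), "\n")
print("VOI sizes (voxels):")
print(manifest["n_voxels"].describe()[["min", "50%", "max"]].round(0).to_string(), "\n")

t = cohort.tumors[0]
print(f"example tumor {t.spec.tumor_id}: grade group {t.spec.grade_group}, "
      f"{t.mask.n_voxels} voxels")
print(f"  site references: fat {t.fat_ref:.1f}, muscle {t.muscle_ref:.1f} (raw units)")
print(f"  T2W volume shape {t.t2w.shape}, spacing {t.t2w.spacing} mm")
print(f"  DW b-values: {t.dw.bvalues}")

# To write the cohort to disk as NIfTI + manifest CSV:
#   from pzrad.synthetic import write_cohort
#   write_cohort(cohort, "cohort_dir/")
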