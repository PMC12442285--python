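"""In-memory end-to-end runs: simulate -> per-patient metrics -> agreement.

These helpers skip the on-disk NIfTI round trip (which `generate_cohort`
covers) so simulation studies over many seeds stay fast.
"""

from __future__ import annotations

import dataclasses

from .agreement import AgreementReport, run_agreement_study
from .metrics import PatientMetricSet, compute_patient_metrics
from .phantom import PhantomConfig, generate_truth, simulate_patient


def simulate_cohort_records(config: PhantomConfig,
                            connectivity: int = 26,
                            min_volumes=(None, 3.0)) -> list[PatientMetricSet]:
    """Simulate a cohort and compute metrics for both readers.

    ``min_volumes`` lists the filter variants to evaluate (None = keep all
    lesions).  Returns one record per patient x reader x variant.
    """
    truth_all = generate_truth(config)
    records: list[PatientMetricSet] = []
    for i in range(config.n_patients):
        vol, _true_mask, mask_a, mask_b, _ = simulate_patient(config, i,
                                                              truth=truth_all[i])
        for mask in (mask_a, mask_b):
            for min_vol in min_volumes:
                records.append(compute_patient_metrics(
                    vol, mask, connectivity=connectivity, min_volume_cm3=min_vol))
    return records


def simulate_agreement_study(config: PhantomConfig,
                             filter_label: str = "all",
                             connectivity: int = 26,
                             min_volumes=(None, 3.0)
                             ) -> dict[str, AgreementReport]:
    """Simulate a cohort and run the agreement battery on one variant."""
    records = simulate_cohort_records(config, connectivity=connectivity,
                                      min_volumes=min_volumes)
    return run_agreement_study(records, filter_label=filter_label)


def with_perturbation(config: PhantomConfig, *,
                      seed: int | None = None,
                      boundary_jitter_mm: float | None = None,
                      small_lesion_omit_prob: float | None = None) -> PhantomConfig:
    """Copy of ``config`` with selected perturbation fields replaced."""
    updates = {}
    if seed is not None:
        updates["seed"] = seed
    if boundary_jitter_mm is not None:
        updates["boundary_jitter_mm"] = boundary_jitter_mm
    if small_lesion_omit_prob is not None:
        updates["small_lesion_omit_prob"] = small_lesion_omit_prob
    return dataclasses.replace(config, **updates)
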