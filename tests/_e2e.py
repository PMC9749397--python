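"""Shared desk-scale end-to-end training run for the acceptance suite.

Study conditions: 40 healthy training phantoms, 5 healthy + 5 lesioned
(40% uptake reduction) holdout subjects, 2,000 training steps with the
desk architecture preset.  Phantom grid and patch width follow the desk
preset (32^3, 8 full sagittal slices) so the run completes on one CPU.
"""

import numpy as np
from scipy import ndimage

from sbpet import abnormality as abn
from sbpet import metrics as met
from sbpet.gan import ArchConfig, LossWeights, ModelBundle, TrainSchedule, train_stage
from sbpet.inference import synthesize_volume
from sbpet.phantom import make_cohort
from sbpet.preprocess import preprocess_subject

GRID = 32
N_TRAIN, N_HEALTHY, N_LESIONED = 40, 5, 5
STEPS = 2000
LESION_REDUCTION = 0.4


def _lesion_core_z(rec, amap) -> float:
    lm = rec.lesion_mask.data > 0
    dist = ndimage.distance_transform_edt(lm, sampling=tuple(rec.pet.spacing))
    core = dist >= 0.5 * dist.max()
    return float(np.nanmean(amap.z_pct.data[core]))


def run_desk_training(seed: int = 2024, steps: int = STEPS) -> dict:
    train = make_cohort(N_TRAIN, grid_size=GRID, lesion_prob=0.0, seed=seed)
    healthy = make_cohort(N_HEALTHY, grid_size=GRID, lesion_prob=0.0, seed=seed + 1)
    lesioned = make_cohort(
        N_LESIONED, grid_size=GRID, lesion_prob=1.0,
        lesion_reduction=LESION_REDUCTION, seed=seed + 2,
    )
    tn = [preprocess_subject(r) for r in train]
    hn = [preprocess_subject(r) for r in healthy]
    ln = [preprocess_subject(r) for r in lesioned]

    arch = ArchConfig.desk(GRID)
    sched = TrainSchedule.desk("pretrain", steps, seed=seed)
    model = train_stage(tn, arch, LossWeights(), sched, val_dataset=hn)
    untrained = ModelBundle.initialize(arch, seed=seed)

    abs_trained, abs_untrained, healthy_mean_z = [], [], []
    for rec, ns in zip(healthy, hn):
        sb = synthesize_volume(ns.mri_z, ns.brain_mask, model)
        sb_un = synthesize_volume(ns.mri_z, ns.brain_mask, untrained)
        abs_trained.append(met.abs_percent(ns.pet_n, sb, ns.brain_mask))
        abs_untrained.append(met.abs_percent(ns.pet_n, sb_un, ns.brain_mask))
        amap = abn.abnormality_analysis(ns.pet_n, sb, ns.brain_mask, ns.gm, ns.wm)
        healthy_mean_z.append(float(np.nanmean(amap.z_pct.data[rec.mask.data > 0])))

    lesion_core_z = []
    for rec, ns in zip(lesioned, ln):
        sb = synthesize_volume(ns.mri_z, ns.brain_mask, model)
        amap = abn.abnormality_analysis(ns.pet_n, sb, ns.brain_mask, ns.gm, ns.wm)
        lesion_core_z.append(_lesion_core_z(rec, amap))

    return {
        "abs_trained": float(np.mean(abs_trained)),
        "abs_untrained": float(np.mean(abs_untrained)),
        "abs_trained_per_subject": abs_trained,
        "healthy_mean_z": healthy_mean_z,
        "lesion_core_z": lesion_core_z,
        "model": model,
    }
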