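import numpy as np
import pytest

from mgmtnet.synthetic_data import PhantomConfig, generate_case_arrays


@pytest.fixture(scope="session")
def phantom_batch():
    """Small deterministic phantom cohort shared across tests."""
    cfg = PhantomConfig(n_cases=12, slices_per_case=2, seed=42)
    images, masks, labels, case_ids = generate_case_arrays(cfg)
    return {"config": cfg, "images": images, "masks": masks,
            "labels": labels, "case_ids": case_ids}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_scale_run():
    """One scaled-down end-to-end run of the full cascaded pipeline.

    120 phantom slices (40 cases x 3), 96x96, base_channels 8, 15 epochs,
    fixed seed; segmentation without augmentation (it converges), the
    classifier with the nine-angle rotation sweep.  Shared session-wide
    because it is by far the most expensive fixture.
    """
    from mgmtnet.classification_model import ClsConfig
    from mgmtnet.data_model import CaseRecord, DatasetManifest, split_cases
    from mgmtnet.pipeline import SliceDataset, run_experiment
    from mgmtnet.segmentation_model import SegConfig
    from mgmtnet.training import ClsTrainConfig, SegTrainConfig

    seed = 0
    cfg = PhantomConfig(n_cases=40, slices_per_case=3, seed=seed)
    images, masks, labels, case_ids = generate_case_arrays(cfg)
    dataset = SliceDataset(images=images, masks=masks, labels=labels,
                           case_ids=case_ids)
    uniq = sorted(set(case_ids))
    case_label = {c: labels[case_ids.index(c)] for c in uniq}
    manifest = DatasetManifest(
        cases=[CaseRecord(case_id=c, modality=cfg.modality,
                          slice_refs=[f"{c}_s"], mask_refs=[f"{c}_m"],
                          label=case_label[c]) for c in uniq],
        modality=cfg.modality)
    split = split_cases(manifest, 0.2, seed=seed)
    train_sorted = sorted(split.train_ids)
    val_cases = train_sorted[:max(1, len(train_sorted) // 5)]
    train_cases = train_sorted[len(val_cases):]
    result = run_experiment(
        dataset, train_cases, val_cases, sorted(split.test_ids),
        SegConfig(input_height=96, input_width=96, base_channels=8, depth=3,
                  latent_dim=32, vae_reduce_channels=8),
        SegTrainConfig(lr0=1e-3, max_epochs=15, seed=seed),
        ClsConfig(input_height=96, input_width=96),
        ClsTrainConfig(seed=seed))
    return {"result": result, "dataset": dataset, "split": split,
            "phantom_config": cfg}
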