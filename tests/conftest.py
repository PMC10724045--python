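import numpy as np
import pytest

from disconseq import GeneratorConfig, default_region_ids, make_biomarker_cohort, make_toy_tractogram


@pytest.fixture
def small_db():
    """Toy streamline database: 4 regions, 20 streamlines on a 24^3 grid."""
    return make_toy_tractogram(20, (24, 24, 24), n_regions=4, seed=0)


@pytest.fixture
def planted_cohort():
    """Small planted-sequence cohort with default (2 SD) separation."""
    cfg = GeneratorConfig(n_subjects=240, n_regions=10, seed=11)
    ids = default_region_ids(10)
    sequence = [ids[j] for j in np.random.default_rng(5).permutation(10)]
    cohort, truth = make_biomarker_cohort(cfg, sequence)
    return cohort, truth


def brute_force_disconnectivity(mask_volume, streamlines, parcellation, region_ids):
    """Independent voxel-by-voxel oracle for the disconnectivity score."""
    totals = {int(r): 0 for r in region_ids}
    disrupted = {int(r): 0 for r in region_ids}
    for s in streamlines:
        vox = [tuple(int(v) for v in p) for p in s]
        labels = {int(parcellation[vox[0]]), int(parcellation[vox[-1]])}
        labels.discard(0)
        hit = any(mask_volume[v] for v in vox)
        for r in labels:
            totals[r] += 1
            if hit:
                disrupted[r] += 1
    return np.array(
        [disrupted[int(r)] / totals[int(r)] if totals[int(r)] else 0.0 for r in region_ids]
    )
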