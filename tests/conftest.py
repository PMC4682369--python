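import pytest

from oglcnac import synthetic
from oglcnac.seq_windows import NEGATIVE, POSITIVE, PeptideWindow


def make_window(fragment: str, label: str = POSITIVE, protein_id: str = "p",
                position: int | None = None) -> PeptideWindow:
    w = len(fragment) // 2
    return PeptideWindow(
        fragment=fragment,
        center_residue=fragment[w],
        label=label,
        protein_id=protein_id,
        position=position if position is not None else w + 1,
    )


@pytest.fixture(scope="session")
def two_motif_dataset():
    """200 positives from two planted motifs against 2000 background
    negatives; the workhorse dataset for clustering and end-to-end tests."""
    spec = synthetic.DatasetSpec(n_pos=200, n_neg=2000, seed=42)
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def fast_config():
    """Training config with a coarse 2x2 SVM grid for quick fits."""
    from oglcnac.two_layer import TrainConfig

    return TrainConfig(seed=0, c_grid=(1.0, 8.0), gamma_grid=(0.03125, 0.125))
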