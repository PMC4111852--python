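import numpy as np
import pytest

from mudpac import ImpactBounds, MutationMatrix, PathwayGraph


@pytest.fixture
def bounds():
    return ImpactBounds(ma_max=5.0, ma_min=0.5, missense_mean=2.0)


def make_matrix(nsy_counts, sy_counts=None, nsy=None, sy=None):
    """Build a MutationMatrix straight from count arrays (impacts default to
    the counts themselves, i.e. unit impact and unit coverage)."""
    nsy_counts = np.asarray(nsy_counts, dtype=np.int64)
    n, m = nsy_counts.shape
    if sy_counts is None:
        sy_counts = np.zeros((n, m), dtype=np.int64)
    else:
        sy_counts = np.asarray(sy_counts, dtype=np.int64)
    nsy = nsy_counts.astype(float) if nsy is None else np.asarray(nsy, dtype=float)
    sy = sy_counts.astype(float) if sy is None else np.asarray(sy, dtype=float)
    genes = [f"g{i}" for i in range(n)]
    samples = [f"s{j}" for j in range(m)]
    return MutationMatrix(genes, samples, nsy, sy, nsy_counts, sy_counts)


def path_graph(pathway_id, genes):
    """A simple path topology g0-g1-...-gk."""
    edges = list(zip(genes[:-1], genes[1:]))
    return PathwayGraph.make(pathway_id, pathway_id, genes, edges)


@pytest.fixture
def toy_maf(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tStart_Position\n"
        "TP53\tS1\tSilent\t100\n"
        "PIK3CA\tS1\tMissense_Mutation\t200\n"
        "BRCA1\tS2\tFrame_Shift_Del\t300\n"
    )
    return p
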