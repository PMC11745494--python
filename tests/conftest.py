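import numpy as np
import pytest

from repseq.io import Clonotype, Repertoire


def make_repertoire(freqs, prefix="c", isotype="IgG", umi_scale=100, **labels):
    """Small repertoire with given frequencies; keys c0, c1, ..."""
    clones = tuple(
        Clonotype(
            cdr3_nt=f"{prefix}{i}",
            v_gene="V1",
            j_gene="J1",
            isotype=isotype,
            umi_count=max(int(round(f * umi_scale)), 1),
            frequency=f,
            **labels,
        )
        for i, f in enumerate(freqs)
    )
    return Repertoire(clones, dict(labels))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
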