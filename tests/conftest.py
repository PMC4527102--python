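from __future__ import annotations

import numpy as np
import pytest

from spcdiff import CountMatrix, DesignColumn, GroupDesign, ProteinMeta


def build_matrix(
    counts: np.ndarray,
    n_control: int,
    n_case: int,
    replicates: int = 1,
    control_label: str = "ctrl",
    case_label: str = "case",
) -> CountMatrix:
    """Assemble a CountMatrix from a (proteins x (samples*replicates))
    array; control-sample columns first, replicates contiguous."""
    counts = np.asarray(counts)
    columns = []
    for j in range(n_control + n_case):
        group = control_label if j < n_control else case_label
        sid = f"{'A' if j < n_control else 'B'}{j:02d}"
        for r in range(1, replicates + 1):
            columns.append(DesignColumn(f"{sid}_r{r}", sid, r, group))
    proteins = tuple(
        ProteinMeta(entry_name=f"PROT{i}", gene_id=f"GENE{i}")
        for i in range(counts.shape[0])
    )
    return CountMatrix(
        proteins=proteins,
        design=GroupDesign(columns=tuple(columns), control_label=control_label),
        counts=counts,
    )


@pytest.fixture
def small_matrix() -> CountMatrix:
    """4 proteins, 2 control + 3 case samples, 2 replicates each."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(4.0, size=(4, 10))
    counts[3] = 0  # one never-observed protein
    return build_matrix(counts, n_control=2, n_case=3, replicates=2)
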