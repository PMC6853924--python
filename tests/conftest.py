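import numpy as np
import pytest

from clonesweep.data_io import (
    CloneTree,
    CloneTreeNode,
    CopyNumberSegment,
    MutationRecord,
    ROOT_PARENT,
)


@pytest.fixture
def mutation_tsv(tmp_path):
    path = tmp_path / "muts.tsv"
    path.write_text(
        "sample\tchrom\tpos\tref\talt\talt_count\tref_count\tgene\n"
        "S1\t7\t140453136\tA\tT\t30\t70\tBRAF\n"
        "S1\t1\t1000\tG\tC\t0\t50\t\n"
        "S1\t2\t2000\tC\tA\t25\t25\t\n"
    )
    return path


@pytest.fixture
def seg_tsv(tmp_path):
    path = tmp_path / "segs.seg"
    path.write_text(
        "Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n"
        "S1\t7\t140000000\t141000000\t500\t1.0\n"
        "S1\t1\t1\t100000000\t900\t0.0\n"
        "S1\t2\t1\t100000000\t900\t0.0\n"
    )
    return path


@pytest.fixture
def purity_tsv(tmp_path):
    path = tmp_path / "purity.tsv"
    path.write_text("sample\tpurity\nS1\t0.8\nS2\t1.0\n")
    return path


def make_tree(parent_ids, n_mutations, prevalences, log_likelihood=None):
    nodes = [
        CloneTreeNode(
            node_id=i,
            parent_id=p if p is not None else ROOT_PARENT,
            n_mutations=m,
            prevalence=v,
        )
        for i, (p, m, v) in enumerate(zip(parent_ids, n_mutations, prevalences))
    ]
    return CloneTree(nodes=nodes, log_likelihood=log_likelihood)


@pytest.fixture
def chain_tree():
    return make_tree([None, 0, 1], [2, 3, 5], [1.0, 0.8, 0.5])


@pytest.fixture
def star_tree():
    return make_tree([None, 0, 0], [0, 3, 5], [1.0, 0.5, 0.4])
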