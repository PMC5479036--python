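import numpy as np
import pytest

from orthored.seqdata import Dataset, SequenceRecord
from orthored.treebuild import read_newick


def make_dataset(seq_ids, outgroup=None, isoform_map=None, residues="MKV"):
    """Dataset of placeholder records; species parsed from 'SPECIES|id' names."""
    records = [
        SequenceRecord(seq_id=s, species_id=s.split("|")[0], residues=residues)
        for s in seq_ids
    ]
    return Dataset(records, outgroup_species=outgroup, isoform_map=isoform_map)


def random_binary_tree(rng: np.random.Generator, leaf_names, min_len=0.05, max_len=1.5):
    """Random rooted binary tree over the given leaves, random branch lengths."""
    nodes = [f"{name}" for name in leaf_names]
    newicks = {name: name for name in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        nodes.pop(j)
        nodes.pop(i)
        la, lb = rng.uniform(min_len, max_len, size=2)
        merged = f"({newicks[a]}:{la:.6f},{newicks[b]}:{lb:.6f})"
        key = f"__{a}__{b}"
        newicks[key] = merged
        nodes.append(key)
    return read_newick(newicks[nodes[0]] + ";")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
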