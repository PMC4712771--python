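import numpy as np
import pandas as pd
import pytest

import hypoxsig as h


@pytest.fixture(scope="session")
def study_run():
    """One full DE run on the default three-condition study design.

    Simulates the 2000-gene untreated/CoCl2/hypoxia design (seed 0) and
    carries every intermediate the downstream stages need; shared
    session-wide because the NB tests dominate runtime.
    """
    design = h.SimulationDesign(n_genes=2000, seed=0)
    cm, truth = h.simulate_counts(design)
    sf = h.estimate_size_factors(cm)
    disp = h.estimate_dispersions(cm, sf)
    de_hyp = h.nbinom_test(cm, sf, disp, "untreated", "hypoxia")
    de_co = h.nbinom_test(cm, sf, disp, "untreated", "cocl2")
    return {
        "design": design,
        "counts": cm,
        "truth": truth,
        "size_factors": sf,
        "dispersions": disp,
        "de_hypoxia": de_hyp,
        "de_cocl2": de_co,
    }


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples, two conditions, all counts positive."""
    counts = pd.DataFrame(
        {
            "a1": [10, 5, 100],
            "a2": [12, 6, 90],
            "b1": [20, 5, 50],
            "b2": [18, 7, 60],
        },
        index=["g1", "g2", "g3"],
        dtype=np.int64,
    )
    cond = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return h.CountMatrix(counts=counts, condition_of=cond)


@pytest.fixture()
def count_files(tmp_path):
    """Valid on-disk count matrix + sample sheet in the study layout."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene\tuntreated_1\tuntreated_2\tuntreated_3"
        "\tCoCl2_1\tCoCl2_2\tCoCl2_3\thypoxia_1\thypoxia_2\thypoxia_3\n"
        "ENSG01\t10\t12\t9\t30\t28\t33\t15\t14\t18\n"
        "ENSG02\t100\t90\t110\t95\t105\t99\t60\t70\t65\n"
        "ENSG03\t5\t6\t4\t5\t7\t6\t5\t4\t6\n"
    )
    sheet = tmp_path / "samples.tsv"
    lines = ["sample\tcondition"]
    for cond, prefix in (("untreated", "untreated"), ("cocl2", "CoCl2"),
                         ("hypoxia", "hypoxia")):
        lines += [f"{prefix}_{i}\t{cond}" for i in (1, 2, 3)]
    sheet.write_text("\n".join(lines) + "\n")
    return counts, sheet
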