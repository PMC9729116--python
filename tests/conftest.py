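import warnings

import numpy as np
import pandas as pd
import pytest

from statescape import ExpressionMatrix, SimConfig
from statescape.simulate import gen_atac, gen_expression, gen_motifs_regulons, gen_spatial

warnings.filterwarnings("ignore", message="Maximum number of iterations")


def small_config(**overrides) -> SimConfig:
    """A light config for unit tests: same planted structure, small sizes."""
    kw = dict(
        n_samples=3, cells_per_sample=150, nuclei_per_sample=200,
        n_genes=600, n_peaks=800, frac_true_links=0.05,
        states=("OPC-like", "AC-like", "MES-like"),
        hubs_per_state=(5, 3), seed=11,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def sim_small():
    cfg = small_config()
    expr, truth = gen_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def sim_small_atac(sim_small):
    cfg, expr, truth = sim_small
    peak_mat, annotation, qc = gen_atac(cfg, truth)
    return cfg, expr, truth, peak_mat, annotation, qc


@pytest.fixture(scope="session")
def sim_small_full(sim_small_atac):
    cfg, expr, truth, peak_mat, annotation, qc = sim_small_atac
    regulons, motifs = gen_motifs_regulons(cfg, truth)
    spatial_map = gen_spatial(cfg, truth)
    return dict(cfg=cfg, expr=expr, truth=truth, peak_mat=peak_mat,
                annotation=annotation, qc=qc, regulons=regulons,
                motifs=motifs, spatial=spatial_map)


def toy_expression(tpm, genes=None, cells=None, protocol="fresh", **meta_cols):
    """Small dense ExpressionMatrix with defaulted metadata."""
    tpm = np.asarray(tpm, dtype=float)
    n_g, n_c = tpm.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cells = cells or [f"c{j}" for j in range(n_c)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["sample_id"] = meta_cols.pop("sample_id", "s0")
    meta["protocol"] = meta_cols.pop("protocol", protocol)
    for k, v in meta_cols.items():
        meta[k] = v
    return ExpressionMatrix(
        tpm=tpm, genes=pd.Index(genes), cells=pd.Index(cells), cell_meta=meta
    )
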