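"""File interchange: dosage matrices, VCF, maps, matrices, configs.

The simulator is self-contained, but the library layer also accepts user
genotypes through a tabular 0/1/2 dosage matrix (TSV, loci x individuals) or
a VCF, pedigrees through CSV, and writes every relationship matrix as square
CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeMap, PanelAssignment
from .population import PopulationState
from .relmat import RelationshipMatrix
from .scheme import BaseConfig, SchemeConfig

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_map_tsv",
    "write_vcf",
    "read_vcf",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_pedigree_csv",
    "write_phenotype_csv",
    "load_scheme_config",
    "load_base_config",
]


def _panel_subset(panels: PanelAssignment, panel: str | None):
    if panel is None:
        return np.arange(panels.n_tracked)
    return panels.panel_index[panel]


def write_dosage_tsv(state: PopulationState, panels: PanelAssignment, path, panel: str | None = None):
    """Loci x individuals 0/1/2 dosage matrix with an individual-ID header."""
    idx = _panel_subset(panels, panel)
    dos = state.alleles[:, 0, idx].astype(np.int16) + state.alleles[:, 1, idx]
    df = pd.DataFrame(
        dos.T,
        index=[f"chr{panels.chromosome[i]}_{int(panels.position_bp[i])}" for i in idx],
        columns=[f"ind{j}" for j in state.ids],
    )
    df.to_csv(path, sep="\t", index_label="locus")


def read_dosage_tsv(path):
    """Returns (dosages (n_individuals, n_loci), individual_ids, locus_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy().T, list(df.columns), list(df.index)


def write_map_tsv(panels: PanelAssignment, path):
    pd.DataFrame(
        {
            "chromosome": panels.chromosome,
            "locus_id": [f"L{i}" for i in range(panels.n_tracked)],
            "genetic_pos_Morgan": panels.position_morgan,
            "physical_pos_bp": panels.position_bp.astype(np.int64),
        }
    ).to_csv(path, sep="\t", index=False)


def write_vcf(state: PopulationState, panels: PanelAssignment, path, panel: str | None = None):
    """Phased diploid VCF of one generation at the tracked (or one panel's) loci."""
    idx = _panel_subset(panels, panel)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gocsim\n")
        for c in sorted(set(int(x) for x in panels.chromosome[idx])):
            fh.write(f"##contig=<ID=chr{c}>\n")
        samples = [f"ind{j}" for j in state.ids]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        a = state.alleles
        for i in idx:
            gts = "\t".join(f"{a[j, 0, i]}|{a[j, 1, i]}" for j in range(state.n))
            fh.write(
                f"chr{panels.chromosome[i]}\t{int(panels.position_bp[i]) + 1}\tL{i}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a (possibly phased) diploid VCF into allele and dosage arrays.

    Returns (alleles (n, 2, L) with -1 for missing, dosages, sample_ids,
    chromosome_labels, positions_bp).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chroms, pos, rows = [], [], []
    for rec in vf:
        gt = np.full((len(samples), 2), -1, dtype=np.int8)
        for j, s in enumerate(samples):
            alleles = rec.samples[s]["GT"]
            for h, al in enumerate(alleles[:2]):
                if al is not None:
                    gt[j, h] = al
        rows.append(gt)
        chroms.append(rec.chrom)
        pos.append(rec.pos)
    alleles = np.stack(rows, axis=2) if rows else np.zeros((len(samples), 2, 0), np.int8)
    dosages = np.where((alleles >= 0).all(axis=1), alleles.sum(axis=1), -1)
    return alleles, dosages, samples, chroms, np.asarray(pos)


def write_matrix_csv(G: RelationshipMatrix, ids, path):
    """Square CSV with ID header row/column plus a JSON metadata sidecar."""
    path = Path(path)
    labels = [str(i) for i in ids]
    pd.DataFrame(G.values, index=labels, columns=labels).to_csv(path, index_label="id")
    sidecar = {
        "name": G.name,
        "kind": G.kind,
        "panel": G.panel,
        "alpha": G.alpha,
        **{k: v for k, v in G.meta.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix_csv(path):
    df = pd.read_csv(path, index_col=0)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return df.to_numpy(), list(df.columns), meta


def write_pedigree_csv(pedigree_frame: pd.DataFrame, path):
    pedigree_frame.to_csv(path, index=False)


def write_phenotype_csv(state: PopulationState, path):
    pd.DataFrame(
        {
            "individual_id": state.ids,
            "generation": state.generation,
            "sex": np.where(state.sex == 0, "M", "F"),
            "role": np.where(state.is_candidate, "candidate", "testsib"),
            "y": state.phenotype,
            "tbv": state.tbv,
        }
    ).to_csv(path, index=False)


def write_gebv_csv(state: PopulationState, gebv: np.ndarray, path):
    """GEBV table for the current candidates: individual_id, generation, gebv."""
    cand = state.candidates()
    pd.DataFrame(
        {"individual_id": state.ids[cand], "generation": state.generation, "gebv": gebv}
    ).to_csv(path, index=False)


def write_contributions_csv(state: PopulationState, gebv, solution, path):
    """Contribution solution export: individual_id, sex, gebv, contribution."""
    cand = state.candidates()
    pd.DataFrame(
        {
            "individual_id": state.ids[cand],
            "sex": np.where(state.sex[cand] == 0, "M", "F"),
            "gebv": gebv,
            "contribution": solution.c,
        }
    ).to_csv(path, index=False)


def load_scheme_config(path) -> SchemeConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SchemeConfig(**raw)


def load_base_config(path_or_dict) -> BaseConfig:
    raw = path_or_dict
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    raw = dict(raw)
    if "genome_map" in raw:
        raw["genome_map"] = GenomeMap(**raw["genome_map"])
    return BaseConfig(**raw)
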