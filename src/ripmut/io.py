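"""Reading call sets and ascus bundles back from disk.

VCFs written by the simulator (or any haploid VCF with GT and DP) are read
through cyvcf2; per-sample depth profiles travel alongside as a compressed
npz so the filtering stage can check coverage at non-called sites.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import PARENTS, SPORES, AscusCalls


def read_vcf_calls(path: str | Path, sample_id: str) -> pd.DataFrame:
    rows = []
    vcf = VCF(str(path))
    for var in vcf:
        if not var.ALT:
            continue
        gts = var.genotypes[0] if var.genotypes else None
        # haploid hom call written as GT "1"; artifacts as "0/1"
        alleles = [g for g in (gts[:-1] if gts else []) if g >= 0]
        zygosity = "hom" if len(set(alleles)) == 1 else "het"
        try:
            depth = int(var.format("DP")[0][0])
        except (TypeError, KeyError):
            depth = 0
        rows.append((
            sample_id, var.CHROM, var.POS, var.REF, var.ALT[0],
            float(var.QUAL or 0.0), depth, zygosity,
        ))
    return pd.DataFrame(rows, columns=[
        "sample_id", "contig", "pos", "ref", "alt", "qual", "depth", "zygosity",
    ])


def save_depth(ascus: AscusCalls, path: str | Path) -> None:
    arrays = {
        f"{sample}::{contig}": arr
        for sample, per_contig in ascus.depth.items()
        for contig, arr in per_contig.items()
    }
    np.savez_compressed(path, **arrays)


def load_depth(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    data = np.load(path)
    depth: dict[str, dict[str, np.ndarray]] = {}
    for key in data.files:
        sample, contig = key.split("::")
        depth.setdefault(sample, {})[contig] = data[key]
    return depth


def load_ascus(vcf_dir: str | Path, ascus_id: int) -> AscusCalls:
    """Rebuild an AscusCalls bundle from a simulate output directory."""
    vcf_dir = Path(vcf_dir)
    frames = []
    for sample in PARENTS + SPORES:
        path = vcf_dir / f"ascus{ascus_id}_{sample}.vcf"
        if not path.exists():
            raise FileNotFoundError(f"missing call set {path}")
        frames.append(read_vcf_calls(path, sample))
    depth = load_depth(vcf_dir / f"ascus{ascus_id}_depth.npz")
    non_empty = [f for f in frames if len(f)] or frames[:1]
    calls = pd.concat(non_empty, ignore_index=True).astype(
        {"pos": int, "qual": float, "depth": int}
    )
    lengths = {c: int(arr.size) for c, arr in depth[PARENTS[0]].items()}
    return AscusCalls(
        ascus_id=ascus_id, calls=calls, depth=depth, contig_lengths=lengths
    )
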