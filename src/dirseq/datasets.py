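"""Bundled demo inputs.

`demo_snp_manifest` builds the 22-SNP design manifest used throughout the
examples and tests: two named cancer-risk SNPs (rs10514231, the risk-T
autophagy-region variant the assay was built around, and rs2089222) plus
twenty synthetic placeholder SNPs with deterministic flanking contexts.  The
placeholder rsIDs and contexts are synthetic stand-ins — the full SNP list
lives in the source study's appendix and is not reproduced here — but the
manifest's shape (22 rows, two alleles each) matches the real library.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

# fixture is frozen: independent of any user-facing seed
_FIXTURE_SEED = 20210721


def _context(rng: np.random.Generator, offset: int = 30, length: int = 61) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def demo_snp_manifest(n_snps: int = 22) -> pd.DataFrame:
    """Deterministic demo manifest with ``n_snps`` rows (default 22)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    named = [
        ("rs10514231", "T", "C", "GWAS catalog"),
        ("rs2089222", "A", "G", "publication"),
    ]
    rows = []
    pairs = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    for i in range(n_snps):
        if i < len(named):
            rsid, risk, prot, source = named[i]
        else:
            risk, prot = pairs[i % len(pairs)]
            rsid, source = f"rs9{900000 + i:06d}", "synthetic placeholder"
        ctx = list(_context(rng))
        ctx[30] = risk  # context shows the risk allele at the SNP position
        rows.append(
            {
                "rsid": rsid,
                "risk_allele": risk,
                "protective_allele": prot,
                "context": "".join(ctx),
                "snp_offset": 30,
                "source": source,
            }
        )
    return pd.DataFrame(rows)


def write_demo_manifest(path: str | Path, n_snps: int = 22) -> Path:
    path = Path(path)
    demo_snp_manifest(n_snps).to_csv(path, sep="\t", index=False)
    return path
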