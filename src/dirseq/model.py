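"""Model/results interface over the reporter-assay statistics.

`DirSeqModel` holds a barcode count table plus the construct design;
`fit()` normalizes activities and applies the regulatory call per SNP per
cell line, returning a `DirSeqResults` with the activity table, the call
table, the log2 fold-change matrix and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calls import CallConfig, RegulatoryCall, call_regulatory, calls_to_frame, fc_matrix
from .design import Construct, NEGATIVE_CONTROL_ID, read_constructs
from .errors import InputError, InsufficientDataError
from .quant import ActivityTable, CountTable, normalize_activity


class DirSeqModel:
    """Reporter-activity model for a barcoded allele library.

    Parameters
    ----------
    counts
        Constructs x samples count table (one plasmid-input column plus
        cell-line replicate cDNA columns).
    constructs
        The construct design table linking construct ids to SNPs and allele
        roles.
    control_id
        Identifier of the insert-free negative control that anchors the
        activity scale.
    """

    def __init__(
        self,
        counts: CountTable,
        constructs: list[Construct],
        control_id: str = NEGATIVE_CONTROL_ID,
        pseudocount: float = 0.0,
        min_input_count: int = 10,
    ) -> None:
        self.counts = counts
        self.constructs = constructs
        self.control_id = control_id
        self.pseudocount = pseudocount
        self.min_input_count = min_input_count
        ids = {c.construct_id for c in constructs}
        missing = ids - set(counts.counts.index)
        if missing:
            raise InputError(f"constructs missing from the count table: {sorted(missing)[:5]}")

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        constructs_path: str | Path,
        **kwargs,
    ) -> "DirSeqModel":
        return cls(
            counts=CountTable.read(counts_path, samples_path),
            constructs=read_constructs(constructs_path),
            **kwargs,
        )

    def fit(self, config: CallConfig | None = None) -> "DirSeqResults":
        config = config or CallConfig()
        activity = normalize_activity(
            self.counts,
            control_id=self.control_id,
            pseudocount=self.pseudocount,
            min_input_count=self.min_input_count,
        )
        by_snp: dict[str, dict[str, str]] = {}
        for c in self.constructs:
            if c.allele_role in ("risk", "protective"):
                by_snp.setdefault(c.rsid_or_control, {})[c.allele_role] = c.construct_id
        cell_lines = activity.samples["cell_line"].unique().tolist()
        calls: list[RegulatoryCall] = []
        skipped: list[tuple[str, str, str]] = []
        for rsid, pair in sorted(by_snp.items()):
            if set(pair) != {"risk", "protective"}:
                skipped.append((rsid, "*", "missing allele construct"))
                continue
            for line in cell_lines:
                cols = activity.samples.loc[
                    activity.samples["cell_line"] == line, "sample"
                ].tolist()
                risk = activity.activity.loc[pair["risk"], cols].to_numpy(float)
                prot = activity.activity.loc[pair["protective"], cols].to_numpy(float)
                try:
                    calls.append(
                        call_regulatory(risk, prot, config, rsid=rsid, cell_line=line)
                    )
                except InsufficientDataError:
                    skipped.append((rsid, line, "insufficient replicates (low input?)"))
        matrix, mask = fc_matrix(calls)
        return DirSeqResults(
            model=self,
            config=config,
            activity=activity,
            calls=calls,
            log2fc_matrix=matrix,
            sig_mask=mask,
            skipped=skipped,
        )


@dataclass
class DirSeqResults:
    """Fitted reporter activities and regulatory-SNP calls."""

    model: DirSeqModel
    config: CallConfig
    activity: ActivityTable
    calls: list[RegulatoryCall]
    log2fc_matrix: pd.DataFrame
    sig_mask: pd.DataFrame
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    @property
    def n_tests(self) -> int:
        return len(self.calls)

    def regulatory_snps(self) -> pd.DataFrame:
        df = self.calls_frame
        if df.empty:
            return df
        return df[df["call"] != "none"].reset_index(drop=True)

    def summary(self) -> str:
        df = self.calls_frame
        lines = [
            "DiR-seq reporter activity — regulatory SNP calls",
            "=" * 58,
            f"constructs: {len(self.model.constructs)}   "
            f"cDNA samples: {self.activity.activity.shape[1]}   "
            f"control: {self.model.control_id}",
            f"call rule: fc < {self.config.fc_low} or fc > {self.config.fc_high}, "
            f"p < {self.config.alpha} ({self.config.test} t-test)",
            f"tests performed: {self.n_tests} (no multiple-testing correction applied)",
            "",
        ]
        if df.empty:
            lines.append("no calls (no complete SNP/cell-line pairs)")
        else:
            sig = self.regulatory_snps()
            lines.append(
                f"regulatory calls: {len(sig)} of {len(df)} "
                f"({len(sig) / len(df):.1%})"
            )
            lines.append("")
            show = df.copy()
            for col, fmt in (("fc", "{:.3f}"), ("log2fc", "{:+.3f}"), ("p_value", "{:.3g}")):
                show[col] = show[col].map(fmt.format)
            lines.append(
                show[["rsid", "cell_line", "fc", "log2fc", "p_value", "call"]].to_string(
                    index=False
                )
            )
        if self.skipped:
            lines.append("")
            lines.append(f"skipped: {len(self.skipped)} SNP/cell-line pairs")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.activity.write(out / "activity.tsv")
        self.calls_frame.to_csv(out / "calls.tsv", sep="\t", index=False)
        self.log2fc_matrix.to_csv(out / "log2fc_matrix.tsv", sep="\t")
        self.sig_mask.to_csv(out / "sig_mask.tsv", sep="\t")

    def plot_heatmap(self, path: str | Path) -> None:
        from .calls import plot_fc_heatmap

        plot_fc_heatmap(self.log2fc_matrix, self.sig_mask, str(path))
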