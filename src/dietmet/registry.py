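"""Registry of NMR metabolite measures.

The registry is the single source of truth for the measure panel: which
columns of the metabolite matrix are absolute concentrations, which are
ratios (and how each ratio is defined over absolute measures), how measures
group into the three Nightingale-style clusters, and which measures failed
quality control.  The packaged default emulates a 231-measure targeted panel
(98 lipoprotein-subclass measures, 52 lipids / fatty acids /
low-molecular-weight metabolites of which 5 are QC-flagged, and 81 ratios);
it is synthetic — names and cluster sizes mimic the platform, values do not
originate from it — and is user-replaceable by any TSV with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

CLUSTER_LIPOPROTEIN = "lipoprotein-subclass"
CLUSTER_LMW = "lipids-fa-lmw"
CLUSTER_RATIO = "ratio"

#: measures named as quality-control failures on the default panel
DEFAULT_QC_FAILURES = (
    "glutamine",
    "pyruvate",
    "glycerol",
    "b_hydroxybutyrate",
    "acetate",
)


@dataclass
class MeasureRegistry:
    """Panel description: one row per measure.

    ``table`` columns: name, cluster, is_ratio, numerator, denominator,
    unit, qc_failed.  Composite ratio numerators/denominators are ``+``-joined
    lists of absolute measure names.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "cluster", "is_ratio", "numerator", "denominator",
                    "unit", "qc_failed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"registry missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dups = self.table.loc[self.table["name"].duplicated(), "name"]
            raise ValueError(f"duplicate measure names: {sorted(set(dups))}")
        abs_names = set(self.absolute_measures)
        for _, row in self.table[self.table["is_ratio"] == 1].iterrows():
            for part in self._ratio_terms(row["numerator"]) + self._ratio_terms(
                row["denominator"]
            ):
                if part not in abs_names:
                    raise ValueError(
                        f"ratio {row['name']!r} references unknown absolute "
                        f"measure {part!r}"
                    )

    @staticmethod
    def _ratio_terms(expr: str) -> list[str]:
        if not isinstance(expr, str) or not expr:
            return []
        return [t.strip() for t in expr.split("+")]

    @classmethod
    def from_tsv(cls, path) -> "MeasureRegistry":
        tab = pd.read_csv(path, sep="\t", dtype={"numerator": str,
                                                 "denominator": str})
        tab["numerator"] = tab["numerator"].fillna("")
        tab["denominator"] = tab["denominator"].fillna("")
        return cls(tab)

    @classmethod
    def default(cls) -> "MeasureRegistry":
        with resources.as_file(
            resources.files("dietmet.data") / "default_registry.tsv"
        ) as p:
            return cls.from_tsv(p)

    # -- views -------------------------------------------------------------
    @property
    def measures(self) -> list[str]:
        return list(self.table["name"])

    @property
    def absolute_measures(self) -> list[str]:
        return list(self.table.loc[self.table["is_ratio"] == 0, "name"])

    @property
    def ratio_measures(self) -> list[str]:
        return list(self.table.loc[self.table["is_ratio"] == 1, "name"])

    @property
    def qc_failed_measures(self) -> list[str]:
        return list(self.table.loc[self.table["qc_failed"] == 1, "name"])

    def cluster_counts(self) -> dict[str, int]:
        return self.table["cluster"].value_counts().to_dict()

    def ratio_definition(self, name: str) -> tuple[list[str], list[str], str]:
        """Numerator terms, denominator terms and unit for a ratio measure."""
        row = self.table.set_index("name").loc[name]
        if not row["is_ratio"]:
            raise KeyError(f"{name!r} is not a ratio measure")
        return (
            self._ratio_terms(row["numerator"]),
            self._ratio_terms(row["denominator"]),
            row["unit"],
        )

    def drop(self, names) -> "MeasureRegistry":
        keep = ~self.table["name"].isin(set(names))
        return MeasureRegistry(self.table.loc[keep].reset_index(drop=True))

    def ratios_depending_on(self, names) -> list[str]:
        """Ratio measures whose definition references any of ``names``."""
        names = set(names)
        out = []
        for _, row in self.table[self.table["is_ratio"] == 1].iterrows():
            terms = set(self._ratio_terms(row["numerator"])) | set(
                self._ratio_terms(row["denominator"])
            )
            if terms & names:
                out.append(row["name"])
        return out
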