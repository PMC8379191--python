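"""Group statistics on the per-animal measurement table.

For each measure: D'Agostino normality per group (recorded), then the
two-tailed Mann-Whitney between age groups; the central-vs-peripheral
stromal macrophage contrast uses a paired two-tailed t-test within animals.
"""

from pathlib import Path

import pandas as pd

from mamspat import stats as st

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

UNPAIRED = (
    "ki67_epithelial_ratio",
    "inter_macrophage_distance_um",
    "t_epi_per100",
    "t_stromal_per_mm2",
    "tls_per_mm2",
)


def main() -> None:
    table = pd.read_csv(RESULTS / "animal_table.csv")
    rows = []
    for measure in UNPAIRED:
        c = st.compare_groups(table, measure)
        rows.append(_row(c))
        print(f"{measure}: U={c.statistic:.1f}, p={c.p_value:.2e}")
    paired = st.compare_groups(
        table, "stromal_mac_density", paired=True,
        paired_measures=("stromal_mac_density_central",
                         "stromal_mac_density_peripheral"),
    )
    rows.append(_row(paired))
    print(f"central vs peripheral (paired t): t={paired.statistic:.2f}, "
          f"p={paired.p_value:.2e}")
    pd.DataFrame(rows).to_csv(RESULTS / "stats_report.csv", index=False)


def _row(c: st.GroupComparison) -> dict:
    row = dict(measure=c.measure, test=c.test, statistic=c.statistic,
               p=c.p_value)
    for name, s in c.group_summaries.items():
        row[f"mean_{name}"] = s["mean"]
        row[f"sd_{name}"] = s["sd"]
        row[f"n_{name}"] = s["n"]
    return row


if __name__ == "__main__":
    main()
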