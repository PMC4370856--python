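#!/usr/bin/env python
"""Descriptive statistics of the 1970-2009 crop price/yield history.

Loads the packaged FAOSTAT-derived series for cocoa, maize, banana, soybean
and rice, rescales each to its current price/yield level, and reports the
dispersion measures that drive everything downstream: banana prices are by
far the most volatile input (CV ~65%, SD ~55 US$/Mg raw), banana yields vary
much less (~22%), and the annual net revenues of rice/soybean/cocoa co-move
while banana revenue has a regime break after the late 1980s.

Writes results/series_stats.csv and results/revenue_correlations.csv.
"""

import pathlib

import pandas as pd

import landfolio as lf
from landfolio.reporting import write_csv
from landfolio.simulate import annual_revenue_table

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = lf.load_series_table()
    _, crops, _ = lf.load_default_specs()

    rows = []
    for cid in table.crops:
        raw = lf.series_stats(table[cid])
        rows.append({"crop_id": cid, "scope": "raw", **raw.to_dict()})
        spec = crops[cid]
        res = lf.series_stats(
            lf.rescale_to_current(table[cid], spec.price, spec.yield_)
        )
        rows.append({"crop_id": cid, "scope": "rescaled", **res.to_dict()})
    stats = pd.DataFrame(rows).drop(columns="n_years")

    rescaled = lf.SeriesTable(
        {
            c: lf.rescale_to_current(table[c], crops[c].price, crops[c].yield_)
            for c in table.crops
        }
    )
    corr = lf.empirical_correlations(annual_revenue_table(crops, rescaled))

    OUT.mkdir(exist_ok=True)
    meta = {"script": "01_series_statistics", "seed": "deterministic"}
    write_csv(OUT / "series_stats.csv", stats, meta)
    write_csv(OUT / "revenue_correlations.csv", corr.to_frame(), meta)

    banana = lf.series_stats(table["banana"])
    print(
        f"banana raw price: mean {banana.price_mean:.1f} US$/Mg, "
        f"SD {banana.price_sd:.1f} (CV {banana.price_cv:.1%}); "
        f"yield CV {banana.yield_cv:.1%}"
    )
    i, j = corr.crop_ids.index("rice"), corr.crop_ids.index("soybean")
    print(f"rice-soybean annual revenue correlation: {corr.values[i, j]:+.2f}")
    print(f"wrote {OUT / 'series_stats.csv'} and {OUT / 'revenue_correlations.csv'}")


if __name__ == "__main__":
    main()
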