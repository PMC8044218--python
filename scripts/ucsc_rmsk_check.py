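#!/usr/bin/env python
"""Optional online check of the RepeatMasker reader against the real
UCSC hg38 table.

Downloads rmsk.txt.gz (~150 MB) from the UCSC goldenPath mirror, runs the
ucsc-dialect reader with an L1PA2 subfamily filter plus the
primary-chromosome filter, and prints the size of the resulting element
universe and the number of copies with genomic span > 6 kb.  Expected on
hg38: 4,940 L1PA2 copies, 978 of them over 6 kb.

Requires network access; everything else in this package runs offline.

Usage:
    python scripts/ucsc_rmsk_check.py [--cache /path/rmsk.txt.gz]
"""

from __future__ import annotations

import argparse
import gzip
import os
import sys
import urllib.request

from repeat_regprof.formats_io import filter_primary_chromosomes

URL = "https://hgdownload.soe.ucsc.edu/goldenPath/hg38/database/rmsk.txt.gz"

# rmsk.txt.gz ships without a header line; these are the schema columns.
RMSK_COLUMNS = ("bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\t"
                "genoStart\tgenoEnd\tgenoLeft\tstrand\trepName\trepClass\t"
                "repFamily\trepStart\trepEnd\trepLeft\tid")


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cache", default="scratch/rmsk.txt.gz",
                        help="Where to store/find the downloaded table.")
    parser.add_argument("--rep-name", default="L1PA2")
    args = parser.parse_args(argv)

    if not os.path.exists(args.cache):
        os.makedirs(os.path.dirname(os.path.abspath(args.cache)), exist_ok=True)
        print(f"downloading {URL} ...", file=sys.stderr)
        urllib.request.urlretrieve(URL, args.cache)

    # prepend the schema header so the reader can address columns by name
    headered = args.cache + ".headered.gz"
    with gzip.open(args.cache, "rt") as src, gzip.open(headered, "wt") as dst:
        dst.write(RMSK_COLUMNS + "\n")
        for line in src:
            dst.write(line)

    from repeat_regprof.formats_io import read_repeatmasker
    records = filter_primary_chromosomes(
        read_repeatmasker(headered, rep_name_filter=args.rep_name,
                          dialect="ucsc"))
    n_total = len(records)
    n_over_6kb = sum(1 for r in records if r.interval.length > 6_000)
    print(f"{args.rep_name} elements on primary chromosomes: {n_total}")
    print(f"{args.rep_name} elements with genomic span > 6 kb: {n_over_6kb}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
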