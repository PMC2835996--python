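"""Build a signed cancer-miRNA network from a TSV edge list and inspect it.

Each row of the edge list reports one dysregulation call: a miRNA that is
up- or downregulated in a cancer type.  Synonyms like "overexpressed" /
"amplified" and "underexpressed" / "deleted" map onto UP and DOWN.
"""

import io

from cminet import read_edge_list, to_transactions, write_pajek

EDGE_LIST = """\
cancer\tmirna\tdirection
breast\tmiR-21\tup
breast\tmiR-125b\tdown
breast\tmiR-100\tdown
colon\tmiR-21\toverexpressed
colon\tmiR-143\tdeleted
brain\tmiR-21\tup
brain\tlet-7a-2\tdown
"""

network = read_edge_list(EDGE_LIST)
print(network)
print("miR-21 is dysregulated in", network.degree("mir-21"), "cancer types:")
for cancer, direction in sorted(network.cancers_of("mir-21").items()):
    print(f"  {cancer}: {direction.value}")

# per-cancer item sets are the input to module mining
db = to_transactions(network)
for cancer, items in db.transactions.items():
    print(f"{cancer}: {sorted(items)}")

# Pajek export: cancers listed first, UP edges solid, DOWN edges dotted
net_buf, clu_buf = io.StringIO(), io.StringIO()
write_pajek(network, net_buf, clu_buf)
print(net_buf.getvalue())
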