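"""Read two activity-table CSVs, unify their descriptor vocabularies,
and apply the optional log(1+x) input transform.

A time-series split leaves the train and test files with different
descriptor columns (all-zero columns are omitted per split); alignment
zero-fills each side so both matrices share one ordered vocabulary.
"""

import tempfile
from pathlib import Path

from qsardnn import align_vocabularies, log_transform, read_activity_table

# descriptor-key column names contain commas, so they are CSV-quoted
train_csv = (
    'MOLECULE,Act,"AP|C(1,0)|1|C(2,0)","AP|C(2,0)|1|O(1,0)"\n'
    "m1,4.5,2,1\nm2,6.1,0,3\n"
)
test_csv = 'MOLECULE,Act,"AP|C(2,0)|1|O(1,0)","AP|C(1,0)|2|O(1,0)"\nm9,5.2,1,4\n'

with tempfile.TemporaryDirectory() as d:
    train_path, test_path = Path(d, "train.csv"), Path(d, "test.csv")
    train_path.write_text(train_csv)
    test_path.write_text(test_csv)
    train = read_activity_table(train_path)
    test = read_activity_table(test_path)

print("train columns:", train.descriptor_names)
print("test columns: ", test.descriptor_names)

aligned = align_vocabularies(train, test)
print("merged vocabulary:", aligned.vocabulary)
print("aligned train matrix:\n", aligned.train.descriptors.to_string(index=False))
print("aligned test matrix:\n", aligned.test.descriptors.to_string(index=False))

logged = log_transform(aligned.train)
print("after log(1+x):\n", logged.descriptors.round(3).to_string(index=False))
print("activities are untouched:", logged.activities.tolist())
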