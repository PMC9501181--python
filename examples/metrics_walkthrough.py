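"""The three evaluation statistics on a worked confusion-count example.

For one image with TP=8, FP=1, FN=1, TN=90:
  IoU   = TP/(TP+FP+FN)            = 0.8
  F1    = 2TP/(2TP+FP+FN)          = 0.8889
  NICE2 = (FN/(FN+TP)+FP/(FP+TN))/2 = 0.0610  (lower is better)
The same numbers fall out of two binary masks built to have those counts.
"""

import numpy as np

from irisseg import ConfusionCounts, confusion_counts, dice_loss, \
    segmentation_metrics

rep = segmentation_metrics([ConfusionCounts(tp=8, fp=1, fn=1, tn=90)])
print(f"from counts : MIOU={rep.miou:.4f}  F1={rep.f1:.4f}  "
      f"NICE2={rep.nice2:.4f}")

# build a 10x10 mask pair realizing exactly those counts
gt = np.zeros((10, 10), dtype=np.uint8)
gt[0, :9] = 1                       # 9 iris pixels
pred = gt.copy()
pred[0, 8] = 0                      # one missed iris pixel  (FN)
pred[5, 5] = 1                      # one false alarm        (FP)
rep2 = segmentation_metrics([confusion_counts(pred, gt)])
print(f"from masks  : MIOU={rep2.miou:.4f}  F1={rep2.f1:.4f}  "
      f"NICE2={rep2.nice2:.4f}")
print(f"dice loss of the same pair: {dice_loss(pred.astype(float), gt):.4f}")
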