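method,split,accuracy,iou,dcs,precision,recall,f1
MGACA,training,98.95,99.55,99.77,99.93,99.99,99.88
DeepLabV3+,training,98.47,97.98,98.98,99.57,99.53,99.57
Unet,training,97.51,99.53,99.43,99.95,99.94,99.94
Res_Unet,training,97.77,92.47,96.09,96.82,96.78,96.80
InceptionV3_Unet,training,95.13,77.97,85.03,93.18,83.16,87.87
VGG19_Unet,training,98.17,98.81,99.91,99.98,99.99,99.92
Nested_Unet,training,96.93,86.41,92.71,93.89,93.81,93.85
Attention_Unet,training,16.33,17.01,29.03,17.01,99.99,29.07
Attention_ResUnet,training,97.71,57.04,72.64,95.13,97.93,96.51
MGACA,validation,98.63,95.39,97.64,98.21,97.50,97.86
DeepLabV3+,validation,97.65,92.45,96.08,96.61,95.94,96.27
Unet,validation,97.65,92.76,92.76,96.38,96.35,96.36
Res_Unet,validation,96.82,87.03,93.06,93.91,93.03,93.46
InceptionV3_Unet,validation,92.48,62.03,76.53,97.66,61.43,75.67
VGG19_Unet,validation,97.06,94.69,96.20,96.87,96.89,96.88
Nested_Unet,validation,96.54,84.88,91.82,90.23,95.73,92.87
Attention_Unet,validation,16.31,16.98,29.03,16.98,99.99,29.02
Attention_ResUnet,validation,96.56,83.89,91.07,94.88,93.95,94.41
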