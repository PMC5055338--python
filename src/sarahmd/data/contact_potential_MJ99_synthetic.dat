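# Synthetic stand-in contact-potential matrix ('MJ99' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
 -2.7745  -1.2253  -1.2178  -1.3647  -3.0896  -1.5669  -1.3071  -2.3817  -1.5645  -3.6509  -3.7265  -1.2220  -2.9419  -3.1533  -1.9137  -2.0554  -2.2658  -2.1536  -2.0272  -3.6312
 -1.2253  -0.4575  -0.9751  -1.3359  -1.0262  -0.8224  -1.4606  -0.9237  -0.9393  -0.9554  -0.9586  -0.3181  -0.9868  -1.0598  -0.9146  -1.0979  -0.9971  -0.8578  -0.9105  -1.0709
 -1.2178  -0.9751  -0.9718  -0.9879  -1.4261  -1.0119  -0.8601  -1.0563  -1.0117  -1.6428  -1.4500  -1.1771  -1.2745  -1.5147  -1.1583  -1.1509  -1.2391  -1.3596  -1.2037  -1.5262
 -1.3647  -1.3359  -0.9879  -0.1604  -1.3780  -1.0283  -0.4060  -1.1052  -1.0144  -1.5437  -1.6826  -1.2650  -1.3046  -1.2974  -1.0951  -1.1288  -1.1675  -1.2059  -0.9870  -1.6014
 -3.0896  -1.0262  -1.4261  -1.3780  -3.5404  -1.3111  -1.4383  -2.4901  -1.6276  -4.0491  -3.8275  -1.2404  -3.0317  -3.5574  -1.9640  -2.4066  -2.4666  -2.2063  -2.0567  -4.0086
 -1.5669  -0.8224  -1.0119  -1.0283  -1.3111  -1.0054  -0.9272  -1.3087  -0.9819  -1.6676  -1.6960  -0.8671  -1.2130  -1.3561  -1.0253  -1.0114  -1.2361  -1.1343  -1.1031  -1.5269
 -1.3071  -1.4606  -0.8601  -0.4060  -1.4383  -0.9272  -0.6229  -1.3096  -1.1489  -1.3862  -1.4810  -1.4511  -1.5397  -1.3902  -0.9127  -1.1057  -1.1905  -1.0988  -1.2642  -1.6045
 -2.3817  -0.9237  -1.0563  -1.1052  -2.4901  -1.3087  -1.3096  -2.0154  -1.0288  -2.8255  -2.6642  -1.2471  -2.3257  -2.4485  -1.6886  -1.6647  -1.6740  -1.6637  -1.3700  -2.6834
 -1.5645  -0.9393  -1.0117  -1.0144  -1.6276  -0.9819  -1.1489  -1.0288  -0.9437  -1.6843  -1.6766  -0.9148  -1.5083  -1.6963  -1.2275  -1.1886  -1.3439  -1.3511  -1.1601  -1.7482
 -3.6509  -0.9554  -1.6428  -1.5437  -4.0491  -1.6676  -1.3862  -2.8255  -1.6843  -4.9546  -4.3575  -1.3508  -3.8064  -4.1137  -2.3868  -2.4930  -2.6369  -2.6402  -2.5242  -4.7730
 -3.7265  -0.9586  -1.4500  -1.6826  -3.8275  -1.6960  -1.4810  -2.6642  -1.6766  -4.3575  -4.6238  -1.2639  -3.3239  -3.7802  -2.1316  -2.7009  -2.5165  -2.5317  -2.3726  -4.4849
 -1.2220  -0.3181  -1.1771  -1.2650  -1.2404  -0.8671  -1.4511  -1.2471  -0.9148  -1.3508  -1.2639  -0.4924  -1.3293  -1.2651  -1.0470  -1.1116  -1.3010  -1.0287  -0.9521  -1.2746
 -2.9419  -0.9868  -1.2745  -1.3046  -3.0317  -1.2130  -1.5397  -2.3257  -1.5083  -3.8064  -3.3239  -1.3293  -3.1291  -3.1732  -2.0085  -2.1982  -2.1850  -2.2046  -2.0770  -3.8606
 -3.1533  -1.0598  -1.5147  -1.2974  -3.5574  -1.3561  -1.3902  -2.4485  -1.6963  -4.1137  -3.7802  -1.2651  -3.1732  -3.3507  -2.0890  -2.3096  -2.2860  -2.1274  -2.0240  -3.9979
 -1.9137  -0.9146  -1.1583  -1.0951  -1.9640  -1.0253  -0.9127  -1.6886  -1.2275  -2.3868  -2.1316  -1.0470  -2.0085  -2.0890  -1.3873  -1.5338  -1.4659  -1.5373  -1.6200  -2.4000
 -2.0554  -1.0979  -1.1509  -1.1288  -2.4066  -1.0114  -1.1057  -1.6647  -1.1886  -2.4930  -2.7009  -1.1116  -2.1982  -2.3096  -1.5338  -1.7718  -1.7074  -1.7886  -1.6827  -2.7767
 -2.2658  -0.9971  -1.2391  -1.1675  -2.4666  -1.2361  -1.1905  -1.6740  -1.3439  -2.6369  -2.5165  -1.3010  -2.1850  -2.2860  -1.4659  -1.7074  -1.5546  -1.5775  -1.5136  -2.4265
 -2.1536  -0.8578  -1.3596  -1.2059  -2.2063  -1.1343  -1.0988  -1.6637  -1.3511  -2.6402  -2.5317  -1.0287  -2.2046  -2.1274  -1.5373  -1.7886  -1.5775  -1.6856  -1.5240  -2.5375
 -2.0272  -0.9105  -1.2037  -0.9870  -2.0567  -1.1031  -1.2642  -1.3700  -1.1601  -2.5242  -2.3726  -0.9521  -2.0770  -2.0240  -1.6200  -1.6827  -1.5136  -1.5240  -1.4307  -2.3930
 -3.6312  -1.0709  -1.5262  -1.6014  -4.0086  -1.5269  -1.6045  -2.6834  -1.7482  -4.7730  -4.4849  -1.2746  -3.8606  -3.9979  -2.4000  -2.7767  -2.4265  -2.5375  -2.3930  -4.8183
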