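scope,scope_id,procedure_id,overall,urban,rural
national,national,via,2.9,3.1,2.6
national,national,via_vili,3.5,3.8,3.0
national,national,carehpv_self,9.4,9.8,8.9
national,national,carehpv_clinician,10.1,10.5,9.3
national,national,hc2_self,11.3,11.7,10.6
national,national,hc2_clinician,11.9,12.5,11.0
national,national,colposcopy,5.0,5.4,4.5
national,national,biopsy,7.6,8.2,6.6
national,national,ecc,6.1,6.5,5.3
national,national,leep,77.6,82.3,70.0
national,national,ckc,280.7,314.7,226.7
national,national,figo1,1088.6,1197.4,915.5
national,national,figo2,1073.5,1235.9,815.0
national,national,figo3,1310.6,1428.1,1123.7
national,national,figo4,1160.7,1276.6,976.1
region,eastern,via,3.3,3.5,2.8
region,eastern,via_vili,3.9,4.2,3.3
region,eastern,carehpv_self,10.4,10.8,9.6
region,eastern,carehpv_clinician,11.2,11.6,10.1
region,eastern,hc2_self,12.4,12.9,11.5
region,eastern,hc2_clinician,13.2,13.8,12.0
region,eastern,colposcopy,5.6,6.0,4.9
region,eastern,biopsy,8.5,9.2,7.1
region,eastern,ecc,6.8,7.3,5.7
region,eastern,leep,86.7,91.7,75.8
region,eastern,ckc,351.0,383.3,278.8
region,eastern,figo1,1354.3,1457.6,1123.0
region,eastern,figo2,1352.4,1506.7,1007.0
region,eastern,figo3,1626.5,1738.0,1376.7
region,eastern,figo4,1444.0,1554.1,1197.4
region,middle,via,2.7,2.9,2.4
region,middle,via_vili,3.2,3.5,2.9
region,middle,carehpv_self,8.9,9.2,8.5
region,middle,carehpv_clinician,9.5,9.9,8.9
region,middle,hc2_self,10.6,11.0,10.1
region,middle,hc2_clinician,11.2,11.7,10.5
region,middle,colposcopy,4.7,5.0,4.3
region,middle,biopsy,7.0,7.5,6.3
region,middle,ecc,5.6,6.0,5.0
region,middle,leep,72.2,76.8,66.7
region,middle,ckc,246.1,285.8,197.6
region,middle,figo1,957.1,1084.1,801.5
region,middle,figo2,937.6,1127.3,705.3
region,middle,figo3,1153.9,1291.0,985.8
region,middle,figo4,1020.5,1155.9,854.6
region,western,via,2.6,2.8,2.4
region,western,via_vili,3.1,3.4,2.8
region,western,carehpv_self,8.6,8.9,8.2
region,western,carehpv_clinician,9.1,9.6,8.7
region,western,hc2_self,10.2,10.6,9.8
region,western,hc2_clinician,10.8,11.3,10.3
region,western,colposcopy,4.6,4.9,4.2
region,western,biopsy,6.8,7.4,6.2
region,western,ecc,5.5,5.9,5.0
region,western,leep,70.1,74.7,65.2
region,western,ckc,214.1,244.3,181.3
region,western,figo1,838.0,934.6,733.0
region,western,figo2,807.6,951.9,650.8
region,western,figo3,1013.5,1117.9,900.1
region,western,figo4,893.5,996.5,781.6
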